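"""A-priori precision of a single-proportion estimate.

For a planned sample of size n and an anticipated proportion p, the
two-sided normal-approximation confidence interval extends

    z * sqrt(p (1 - p) / n)

either side of the observed proportion, z being the two-sided normal
quantile for the confidence level (1.959964 at 95%). With n = 400 and
p <= 0.4 the half-width stays below 0.05, which is the precision argument
behind a ~400-sample screening campaign.
"""

from __future__ import annotations

import math

from scipy import stats

__all__ = ["ci_half_width", "min_n_for_half_width"]


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def ci_half_width(p_expected: float, n: int, level: float = 0.95) -> float:
    """Half-width (proportion scale) of the Wald CI at the planned n."""
    if not 0.0 <= p_expected <= 1.0:
        raise ValueError(f"p_expected must be in [0, 1], got {p_expected!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    return _z(level) * math.sqrt(p_expected * (1.0 - p_expected) / n)


def min_n_for_half_width(
    p_expected: float, target_half_width: float, level: float = 0.95
) -> int:
    """Smallest n whose Wald half-width does not exceed the target.

    Inverts the closed form, ``ceil(z^2 p (1-p) / w^2)``, then walks the
    boundary so the returned n satisfies the bound and n − 1 does not
    (degenerate p gives n = 1).
    """
    if target_half_width <= 0.0:
        raise ValueError(
            f"target_half_width must be > 0, got {target_half_width!r}"
        )
    if not 0.0 <= p_expected <= 1.0:
        raise ValueError(f"p_expected must be in [0, 1], got {p_expected!r}")
    z = _z(level)
    n = max(
        1,
        math.ceil(z * z * p_expected * (1.0 - p_expected) / target_half_width**2),
    )
    # guard against float edge cases at the boundary
    while ci_half_width(p_expected, n, level) > target_half_width:
        n += 1
    while n > 1 and ci_half_width(p_expected, n - 1, level) <= target_half_width:
        n -= 1
    return n
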