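"""Synthetic reconstructions of the published summary tables.

These fixtures rebuild, from the printed per-substance prevalence table and
the printed drug-combination table of the two-hut screening study, the
minimal data structures the estimators consume. They are *synthetic*: the
underlying per-sample assay data were never published, so the fixtures
encode only what the tables print (counts, shares, concentration moments),
laid out as per-sample positive statuses where the estimators need them.

Note: the printed combination table spells one glucocorticoid
"methylprednisone"; it is normalised here to "methylprednisolone" to match
the prevalence table.
"""

from __future__ import annotations

import hashlib

import pandas as pd

__all__ = [
    "STUDY_N_TOTAL",
    "TABLE1_CLASS_ROWS",
    "table1_fixture",
    "table2_fixture",
    "table2_checksum",
    "class_members_from_table1",
]

#: Samples analysed in the published campaign (274 Goûter + 156 Cosmiques).
STUDY_N_TOTAL = 430
SITE_GOUTER = "gouter"
SITE_COSMIQUES = "cosmiques"

# substance, class, both-huts % (CI low, high; None when not printed),
# concentration mean, sd, min, max (ng/ml; sd/min/max None when n = 1).
_TABLE1_ROWS = (
    ("acetazolamide", "diuretics", 20.6, 16.5, 24.7, 44630.0, 96857.0, 20.0, 491100.0),
    ("hydrochlorothiazide", "diuretics", 1.6, 0.4, 2.9, 1935.0, 3620.0, 4.0, 10048.0),
    ("zolpidem", "hypnotics", 8.4, 5.6, 11.2, 9.0, 23.0, 0.1, 127.0),
    ("oxazepam", "hypnotics", 1.6, 0.3, 2.8, 67.0, 85.0, 3.0, 222.0),
    ("zopiclone", "hypnotics", 1.3, 0.2, 2.4, 185.0, 313.0, 11.0, 739.0),
    ("lorazepam", "hypnotics", 0.5, 0.0, 1.3, 2858.0, 3816.0, 160.0, 5556.0),
    ("bromazepam", "hypnotics", 0.3, None, None, 23.0, None, 23.0, 23.0),
    ("zaleplon", "hypnotics", 0.3, None, None, 3.0, None, 3.0, 3.0),
    ("brotizolam", "hypnotics", 0.3, None, None, 1.0, None, 1.0, 1.0),
    ("prednisone", "glucocorticoids", 1.9, 0.6, 3.2, 391.0, 306.0, 11.0, 776.0),
    ("prednisolone", "glucocorticoids", 1.6, 0.4, 2.9, 939.0, 1346.0, 11.0, 3823.0),
    ("betamethasone", "glucocorticoids", 0.7, 0.0, 1.5, 25.0, 15.0, 13.0, 42.0),
    ("budesonide", "glucocorticoids", 0.5, 0.0, 1.1, 15.0, 6.0, 11.0, 19.0),
    ("methylprednisolone", "glucocorticoids", 0.5, 0.0, 1.1, 639.0, 831.0, 51.0, 1226.0),
    ("caffeine", "stimulants", 0.9, 0.0, 1.8, 7725.0, 629.0, 7000.0, 8300.0),
    ("benzoylecgonine", "stimulants", 0.7, 0.0, 1.5, 253.0, 263.0, 68.0, 439.0),
    ("pseudoephedrine", "stimulants", 0.5, 0.0, 1.1, 10940.0, 14228.0, 879.0, 21000.0),
    ("ephedrine", "stimulants", 0.2, None, None, 9.0, None, 9.0, 9.0),
    ("N-ethylnicotinamide", "stimulants", 0.2, None, None, 299.0, None, 299.0, 299.0),
    ("heptaminol", "stimulants", 0.2, None, None, 127.0, None, 127.0, 127.0),
    ("dihydrobupropion", "stimulants", 0.2, None, None, 665.0, None, 665.0, 665.0),
    ("THC", "cannabinoids", 3.8, 2.0, 5.7, 44.0, 44.0, 8.0, 152.0),
    ("codeine", "narcotics", 1.9, 0.6, 3.2, 379.0, 490.0, 11.0, 1297.0),
    ("morphine", "narcotics", 1.9, 0.6, 3.2, 70.0, 91.0, 6.0, 274.0),
    ("methadone", "narcotics", 0.2, None, None, 5.0, None, 5.0, 5.0),
    ("hydrocodone", "narcotics", 0.2, None, None, 480.0, None, 480.0, 480.0),
    ("tramadol", "narcotics", 0.2, None, None, 358.0, None, 358.0, 358.0),
    ("betaxolol", "beta-blockers", 0.5, 0.0, 1.1, 201.0, 16.0, 190.0, 212.0),
    ("metoprolol", "beta-blockers", 0.5, 0.0, 1.1, 44.0, 14.0, 34.0, 54.0),
    ("metoprolol acid", "beta-blockers", 0.5, 0.0, 1.1, 109.0, 129.0, 17.0, 200.0),
    ("bisoprolol", "beta-blockers", 0.2, None, None, 64.0, None, 64.0, 64.0),
    ("methoxytamoxifen", "metabolic modulators", 0.2, None, None, 25.0, None, 25.0, 25.0),
    ("anastrozole", "metabolic modulators", 0.2, None, None, 250.0, None, 250.0, 250.0),
)

#: Printed class-level adjusted prevalences, both huts: % (CI low, high).
TABLE1_CLASS_ROWS = {
    "diuretics": (22.7, 18.5, 27.0),
    "hypnotics": (12.9, 9.5, 16.4),
    "glucocorticoids": (3.5, 1.8, 5.3),
    "stimulants": (3.1, 1.4, 4.7),
    "narcotics": (2.6, 1.1, 4.1),
    "beta-blockers": (1.2, 0.1, 2.2),
    "metabolic modulators": (0.5, 0.0, 1.1),
}

# combination rows: substances, Goûter count, Cosmiques count.
_TABLE2_ROWS = (
    (("acetazolamide", "zolpidem"), 5, 2),
    (("acetazolamide", "hydrochlorothiazide"), 2, 2),
    (("acetazolamide", "prednisone"), 3, 1),
    (("acetazolamide", "betamethasone"), 3, 0),
    (("acetazolamide", "methylprednisolone"), 0, 1),
    (("acetazolamide", "metoprolol"), 1, 0),
    (("acetazolamide", "zopiclone"), 0, 1),
    (("acetazolamide", "zolpidem", "bisoprolol"), 0, 1),
    (("acetazolamide", "benzoylecgonine", "pseudoephedrine"), 1, 0),
    (("acetazolamide", "codeine", "hydrocodone"), 1, 0),
    (("zolpidem", "caffeine"), 1, 0),
    (("zolpidem", "prednisone"), 1, 0),
    (("zolpidem", "THC"), 0, 1),
    (("zolpidem", "zaleplon"), 0, 1),
    (("zolpidem", "codeine"), 0, 1),
    (("zolpidem", "dihydrobupropion"), 1, 0),
    (("prednisone", "THC"), 0, 1),
    (("hydrochlorothiazide", "prednisone", "benzoylecgonine"), 1, 0),
)

_TABLE2_SHA256 = (
    "f1dd01599ea65e62d52e1440b507901728a12826558d2bb27b1b2aaa11a88e07"
)


def table1_fixture() -> pd.DataFrame:
    """Printed per-substance prevalence and concentration summary rows."""
    return pd.DataFrame.from_records(
        _TABLE1_ROWS,
        columns=[
            "substance", "drug_class", "both_pct", "ci_low_pct", "ci_high_pct",
            "conc_mean", "conc_sd", "conc_min", "conc_max",
        ],
    )


def class_members_from_table1(drug_class: str) -> list[str]:
    members = [r[0] for r in _TABLE1_ROWS if r[1] == drug_class]
    if not members:
        raise KeyError(f"unknown drug class {drug_class!r}")
    return members


def table2_fixture() -> pd.DataFrame:
    """Per-(sample, substance) positive statuses for the printed combinations.

    Each printed combination count is expanded into that many synthetic
    samples, each positive for exactly the combination's substances, placed
    at the printed site. The layout feeds
    :func:`anonprev.prevalence.combination_table` directly; pass
    ``n_total=STUDY_N_TOTAL`` to recover the printed percentages.
    """
    records = []
    sample_no = 0
    for substances, n_gouter, n_cosmiques in _TABLE2_ROWS:
        for site, count in ((SITE_GOUTER, n_gouter), (SITE_COSMIQUES, n_cosmiques)):
            for _ in range(count):
                sample_no += 1
                for substance in substances:
                    records.append(
                        {
                            "site_id": site,
                            "cassette_id": f"t2-{sample_no:03d}",
                            "slot": 1,
                            "substance": substance,
                            "status": "positive",
                        }
                    )
    df = pd.DataFrame.from_records(records)
    if table2_checksum(df) != _TABLE2_SHA256:
        raise RuntimeError("combination-table fixture failed its checksum")
    return df


def table2_checksum(df: pd.DataFrame | None = None) -> str:
    """SHA-256 of the fixture's canonical CSV serialisation."""
    if df is None:
        df = table2_fixture()
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
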