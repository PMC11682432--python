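"""Patient-level cohort tables and csPCa label derivation.

A cohort table is a pandas DataFrame with one row per patient and the
columns ``patient_id``, ``grade_group`` (0 = benign pathology, 1-5 =
Gleason grade group, NaN = no biopsy), ``pirads`` (1-5 radiologist score
or NaN), and ``biopsy`` (whether any pathology is available).

The csPCa label follows two clinical rules:

* biopsied patients: csPCa iff grade group >= 2;
* patients with PI-RADS 1-2 and no biopsy: negative.

Patients matching neither rule (e.g. PI-RADS >= 3 without biopsy) cannot
be labeled and are flagged for exclusion.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "derive_cspca_labels",
    "cohort_from_composition",
    "COHORT1_COMPOSITION",
    "COHORT2_COMPOSITION",
]

#: Radiologic/pathologic composition of the two development cohorts the
#: bundled protocols are modeled on: grade-group counts among biopsied
#: patients, and PI-RADS counts among patients with no biopsy.
COHORT1_COMPOSITION = {
    "grade_groups": {0: 17, 1: 2, 2: 9, 3: 8, 4: 1, 5: 4},
    "no_biopsy_pirads": {1: 4, 2: 1},
}
COHORT2_COMPOSITION = {
    "grade_groups": {0: 38, 1: 30, 2: 40, 3: 32, 4: 7, 5: 17},
    "no_biopsy_pirads": {1: 27, 2: 4},
}


def cohort_from_composition(composition: dict, tag: str = "cohort") -> pd.DataFrame:
    """Expand aggregate grade-group / PI-RADS counts into a patient table."""
    rows = []
    k = 0
    for gg, count in sorted(composition["grade_groups"].items()):
        for _ in range(int(count)):
            rows.append(
                {
                    "patient_id": f"{tag}_{k:03d}",
                    "grade_group": int(gg),
                    "pirads": None,
                    "biopsy": True,
                }
            )
            k += 1
    for pirads, count in sorted(composition.get("no_biopsy_pirads", {}).items()):
        for _ in range(int(count)):
            rows.append(
                {
                    "patient_id": f"{tag}_{k:03d}",
                    "grade_group": None,
                    "pirads": int(pirads),
                    "biopsy": False,
                }
            )
            k += 1
    df = pd.DataFrame(rows)
    df["cohort"] = tag
    return df


def derive_cspca_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Attach ``cspca`` (nullable boolean) and ``excluded`` columns.

    Pure function of the table: row order does not matter and reapplying
    it is a no-op.  Contradictory rows (a grade group recorded while the
    biopsy flag says none exists) raise.
    """
    required = {"grade_group", "pirads", "biopsy"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"cohort table lacks columns: {sorted(missing)}")
    out = table.copy()
    gg = pd.to_numeric(out["grade_group"], errors="coerce")
    pirads = pd.to_numeric(out["pirads"], errors="coerce")
    biopsy = out["biopsy"].astype("boolean")

    contradiction = gg.notna() & (biopsy == False)  # noqa: E712
    if contradiction.any():
        bad = out.loc[contradiction, "patient_id"].tolist()
        raise ValueError(
            f"grade group present but biopsy marked absent for: {bad}"
        )

    label = pd.Series(pd.NA, index=out.index, dtype="boolean")
    label[gg.notna()] = gg[gg.notna()] >= 2
    unbiopsied_low = gg.isna() & (biopsy != True) & pirads.notna() & (pirads <= 2)  # noqa: E712
    label[unbiopsied_low] = False

    out["cspca"] = label
    out["excluded"] = label.isna()
    return out
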