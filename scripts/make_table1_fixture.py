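"""Build the deterministic Table-1 cohort fixture CSV from the printed
per-stratum counts (164 MSS / 24 MSI-H), encoding unaccounted-for cells
as missing. Run from repo root; writes src/msilike/data/table1_cohort.csv."""

import pandas as pd

# variable -> stratum -> list of (level_or_None, count); counts per stratum
# must sum to the stratum size (missing rows fill the gap)
COUNTS = {
    "sex": {
        "MSS": [("male", 93), ("female", 71)],
        "MSI-H": [("male", 13), ("female", 11)],
    },
    "age": {  # numeric stand-ins: 50 for <65, 70 for >=65
        "MSS": [(50.0, 96), (70.0, 68)],
        "MSI-H": [(50.0, 15), (70.0, 9)],
    },
    "mucinous": {
        "MSS": [("no", 138), ("yes", 26)],
        "MSI-H": [("no", 14), ("yes", 10)],
    },
    "differentiation": {
        "MSS": [("poor", 29), ("moderate_to_well", 129), (None, 6)],
        "MSI-H": [("poor", 11), ("moderate_to_well", 11), (None, 2)],
    },
    "t_stage": {
        "MSS": [("T3", 78), ("T4", 86)],
        "MSI-H": [("T3", 10), ("T4", 14)],
    },
    "tumor_site": {
        "MSS": [("right", 36), ("left", 49), ("rectum", 78), (None, 1)],
        "MSI-H": [("right", 16), ("left", 3), ("rectum", 5)],
    },
    "lymphovascular_invasion": {
        "MSS": [("no", 128), ("yes", 36)],
        "MSI-H": [("no", 21), ("yes", 3)],
    },
    "perineural_invasion": {
        "MSS": [("no", 119), ("yes", 45)],
        "MSI-H": [("no", 17), ("yes", 7)],
    },
    "cea": {  # numeric stand-ins: 2.0 for <5, 8.0 for >=5
        "MSS": [(2.0, 108), (8.0, 56)],
        "MSI-H": [(2.0, 16), (8.0, 8)],
    },
    "chemotherapy": {
        "MSS": [("no", 68), ("yes", 96)],
        "MSI-H": [("no", 8), ("yes", 16)],
    },
    "radiotherapy": {
        "MSS": [("no", 142), ("yes", 13), (None, 9)],
        "MSI-H": [("no", 21), ("yes", 2), (None, 1)],
    },
}

SIZES = {"MSS": 164, "MSI-H": 24}
COLMAP = {"age": "age_years", "cea": "cea_ng_ml"}


def expand(variable, stratum):
    vals = []
    for level, count in COUNTS[variable][stratum]:
        vals.extend([level] * count)
    assert len(vals) == SIZES[stratum], (variable, stratum, len(vals))
    return vals


def main():
    rows = []
    idx = 0
    for stratum in ("MSS", "MSI-H"):
        cols = {v: expand(v, stratum) for v in COUNTS}
        for i in range(SIZES[stratum]):
            idx += 1
            row = {"patient_id": f"T{idx:04d}"}
            for v in COUNTS:
                row[COLMAP.get(v, v)] = cols[v][i]
            row["msi_label"] = stratum
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv("src/msilike/data/table1_cohort.csv", index=False)
    print(f"wrote {len(df)} rows")


if __name__ == "__main__":
    main()
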