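"""Morphological risk factors per slice: LA, PA, PB, MinCapT, MeanCapT.

Reads the contour files from 01 and writes results/morphology.csv.
"""

from pathlib import Path

import pandas as pd

from capmech.contours import morphology, read_slice

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for p in sorted((OUT / "contours").glob("*.json")):
        slc = read_slice(p)
        m = morphology(slc)
        rows.append(
            {"slice_id": slc.slice_id, "timepoint": slc.timepoint,
             "LA": m.LA, "PA": m.PA, "PB": m.PB,
             "MinCapT": m.MinCapT, "MeanCapT": m.MeanCapT}
        )
    df = pd.DataFrame(rows).set_index(["slice_id", "timepoint"])
    df.to_csv(OUT / "morphology.csv")
    base = df.xs("baseline", level="timepoint")
    print(f"morphology for {len(df)} slices -> results/morphology.csv")
    print(base.describe().loc[["mean", "std"]].round(3))


if __name__ == "__main__":
    main()
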