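"""Summarize the SV compendium written by 01_run_pipeline.py: class
fractions, repeat-period bins, uniqueness counts, region distribution."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    comp = pd.read_csv(RESULTS / "run" / "compendium.tsv", sep="\t", keep_default_na=False)
    svs = comp[comp["is_sv"] == 1]
    blocks = []
    blocks.append(svs["class"].value_counts(normalize=True).rename("fraction").to_frame())
    blocks.append(
        svs.loc[svs["repeat_bin"] != "", "repeat_bin"]
        .value_counts()
        .rename("n_loci")
        .to_frame()
    )
    blocks.append(svs["region"].value_counts().rename("n_loci").to_frame())
    blocks.append(
        svs.loc[svs["unique_to"] != "", "unique_to"]
        .value_counts()
        .sort_index()
        .rename("n_unique_svs")
        .to_frame()
    )
    out = RESULTS / "compendium_summary.txt"
    with open(out, "w") as fh:
        fh.write(f"SV loci: {len(svs)} of {len(comp)} variant loci\n")
        fh.write(f"fully assessed: {int(svs['fully_assessed'].sum())}\n\n")
        for b in blocks:
            fh.write(b.to_string() + "\n\n")
    print(out.read_text())


if __name__ == "__main__":
    main()
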