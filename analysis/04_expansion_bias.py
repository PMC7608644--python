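"""Per-haplotype expansion/contraction asymmetry from the pairwise
smaller-than matrix of the pipeline run."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    smaller = pd.read_csv(RESULTS / "run" / "expansion_smaller.tsv", sep="\t")
    m = smaller.to_numpy()
    table = pd.DataFrame(
        {
            "haplotype": range(m.shape[0]),
            "times_smaller": m.sum(axis=1),
            "times_larger": m.sum(axis=0),
        }
    )
    table["net_expansion"] = table["times_larger"] - table["times_smaller"]
    out = RESULTS / "expansion_bias.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
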