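"""Tabulate subtelomeric density folds from the pipeline run."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    enr = pd.read_csv(RESULTS / "run" / "enrichment.tsv", sep="\t")
    enr["density_in_per_mb"] = (enr["count_in"] / enr["mb_in"]).round(3)
    enr["density_out_per_mb"] = (enr["count_out"] / enr["mb_out"]).round(3)
    out = RESULTS / "subtelomeric_enrichment.tsv"
    enr.to_csv(out, sep="\t", index=False)
    print(enr.to_string(index=False))


if __name__ == "__main__":
    main()
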