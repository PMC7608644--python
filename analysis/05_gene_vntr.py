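"""Gene-level VNTR burden versus brain expression from the pipeline run."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from svscape.landscape import spearman

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genes = pd.read_csv(RESULTS / "run" / "genes.tsv", sep="\t")
    r_len, p_len = spearman(genes["length_bp"], genes["log10_tpm"])
    r_v, p_v = spearman(genes["vntr_count"], genes["log10_tpm"])
    top = genes.nlargest(15, "vntr_count")[
        ["gene_id", "chrom", "length_bp", "vntr_count", "mean_brain_tpm", "subtelomeric"]
    ]
    out = RESULTS / "gene_vntr.txt"
    with open(out, "w") as fh:
        fh.write(f"genes analysed: {len(genes)}\n")
        fh.write(f"length vs log10 brain TPM: r={r_len:.3f} p={p_len:.2e}\n")
        fh.write(f"VNTR count vs log10 brain TPM: r={r_v:.3f} p={p_v:.2e}\n\n")
        fh.write("most VNTR-dense genes:\n")
        fh.write(top.to_string(index=False) + "\n")
    print(out.read_text())


if __name__ == "__main__":
    main()
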