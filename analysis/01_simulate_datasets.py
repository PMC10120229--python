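"""Generate the two synthetic datasets used by the downstream analyses.

Writes a multi-sample two-condition NB dataset (with DE-gene truth) and a
multi-cell-type marker/housekeeping dataset (with gene-class truth) as
MTX + TSV under results/data/.
"""

import argparse
from pathlib import Path

import pandas as pd

from scbinary import SimConfig, simulate_celltypes, simulate_multisample, write_counts_mtx


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    ms_dir = args.out / "multisample"
    m, truth = simulate_multisample(SimConfig(seed=args.seed))
    write_counts_mtx(m, ms_dir)
    pd.DataFrame(
        {"gene_id": m.gene_ids, "is_de": truth.is_de, "lfc": truth.lfc}
    ).to_csv(ms_dir / "truth.tsv", sep="\t", index=False)
    print(
        f"multisample: {m.n_genes} genes x {m.n_cells} cells, "
        f"{int(truth.is_de.sum())} DE genes -> {ms_dir}"
    )

    ct_dir = args.out / "celltypes"
    m2, truth2 = simulate_celltypes(seed=args.seed)
    write_counts_mtx(m2, ct_dir)
    truth2.to_csv(ct_dir / "truth.tsv", sep="\t", index=False)
    markers = truth2[truth2.gene_class == "marker"][["marker_type", "gene_id"]]
    markers.rename(columns={"marker_type": "cell_type"}).to_csv(
        ct_dir / "markers.tsv", sep="\t", index=False
    )
    print(
        f"celltypes: {m2.n_genes} genes x {m2.n_cells} cells, "
        f"{len(set(m2.celltype_of_cell))} types -> {ct_dir}"
    )


if __name__ == "__main__":
    main()
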