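#!/usr/bin/env python
"""Overlap enrichment and methylation metaprofiles.

Scores the observed:expected overlap between called hyperactivated genes
and the planted hyper set (Fisher's exact test), and writes CG
metaprofiles (1 kb flanks, 40 body bins) around genes with planted GBM
versus unmethylated genes. Writes results/enrichment.tsv and
results/metaprofile_cg.tsv.
"""

from pathlib import Path

import pandas as pd

from gbmscan.enrichment import metaprofile, overlap_enrichment
from gbmscan.io import read_cx_report, read_gene_annotation

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    priming = pd.read_csv(ROOT / "priming.tsv", sep="\t", index_col=0)
    universe = list(priming.index)
    called_hyper = list(priming.index[priming["priming_category"] == "DDM1_HYPER"])
    planted_hyper = list(priming.index[priming["planted_role"] == "hyper"])
    res = overlap_enrichment(called_hyper, planted_hyper, universe)
    pd.DataFrame([res.__dict__]).to_csv(ROOT / "enrichment.tsv", sep="\t", index=False)
    print(
        f"called-hyper vs planted-hyper overlap: {res.observed_overlap} observed, "
        f"{res.expected:.1f} expected ({res.ratio:.1f}-fold, p = {res.p:.2e})"
    )

    wildtype = read_cx_report(ROOT / "sim" / "methylome_wildtype.cx.tsv", genotype="wildtype")
    genes = read_gene_annotation(ROOT / "sim" / "genes.bed")
    truth = pd.read_csv(ROOT / "sim" / "truth_genes.tsv", sep="\t").set_index("gene_id")
    gbm_ids = set(truth.index[truth["true_category"] == "GBM"])
    none_ids = set(truth.index[truth["true_category"] == "NONE"])
    profiles = []
    for label, ids in (("GBM", gbm_ids), ("unmethylated", none_ids)):
        prof = metaprofile(wildtype, [g for g in genes if g.gene_id in ids], "CG")
        prof.insert(0, "group", label)
        profiles.append(prof)
    out = pd.concat(profiles, ignore_index=True)
    out.to_csv(ROOT / "metaprofile_cg.tsv", sep="\t", index=False)
    body = out[out["zone"] == "body"].groupby("group")["level"].mean()
    print("mean body CG level by gene group:")
    print(body.to_string())


if __name__ == "__main__":
    main()
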