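"""Link promoter deletions and allele-specific ACRs to ASE genes.

Runs the full pipeline on a small synthetic study, then shows the two
phase-block-restricted linkage analyses: the Hedges' G permutation test for
higher expression of the deletion-carrying allele when the deletion sits in
the promoter, and the correlation between allelic accessibility and allelic
expression for nearby AS-ACR:gene pairs.
"""
import json
import tempfile
from pathlib import Path

from haplocis import pipeline
from haplocis.config import RunConfig, SimConfig

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(seed=11, simulate=SimConfig(), ase_n_sims=1000, n_perm=1000)
    pipeline.run(None, cfg, tmp)
    stats = json.loads((Path(tmp) / "link_stats.json").read_text())

    pd_link = stats.get("promoter_deletion")
    if pd_link:
        print(f"promoter-deletion effect: Hedges G = {pd_link['hedges_g']:.3f}, "
              f"permutation p = {pd_link['p']:.4f} "
              f"({pd_link['n_promoter']} promoter vs {pd_link['n_other']} other pairs)")
    corr = stats["acr_gene_correlation"]
    if corr["r"] is not None:
        print(f"AS-ACR : ASE-gene allelic correlation: r = {corr['r']:.3f}, "
              f"p = {corr['p']:.2e} over {corr['n']} same-block pairs within 5 kb")
# A positive Hedges G means the deletion-carrying allele is expressed higher;
# the ACR:gene correlation recovers the simulated shared allelic driver.
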