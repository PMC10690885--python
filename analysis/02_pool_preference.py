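#!/usr/bin/env python
"""Score each phage's major capsid protein gene under candidate tRNA pools.

Reads the panel written by 01_simulate_panel.py, computes the gene's tAI
under the host pool and under the phage's own pool (the helper's pool for
satellites), runs the exact Wilcoxon signed-rank test on the paired
differences for the ordinary phages, and writes the per-phage table and a
Fig.-style bar chart under results/.
"""

from pathlib import Path

from poolfit import PairManifest, compare_pools, read_genomes, signed_rank_test
from poolfit.cli import _plot_comparison

ROOT = Path(__file__).resolve().parent.parent / "results"
PANEL = ROOT / "panel"

genomes = read_genomes(sorted(PANEL.glob("*.gbk")))
manifest = PairManifest.from_tsv(PANEL / "manifest.tsv")
result = compare_pools(genomes, manifest)

pair_rows = [r for r in result.rows if r.alt_pool == "self"]
sat_rows = [r for r in result.rows if r.alt_pool == "helper"]
sr = signed_rank_test([r.tai_alt - r.tai_host for r in pair_rows])

table = ROOT / "pool_preference.tsv"
with open(table, "w") as fh:
    fh.write("phage_id\ttai_host\ttai_alt\talt_pool\tdifference\n")
    for r in result.rows:
        fh.write(f"{r.phage_id}\t{r.tai_host:.6f}\t{r.tai_alt:.6f}\t{r.alt_pool}"
                 f"\t{r.tai_alt - r.tai_host:.6f}\n")
_plot_comparison(result, ROOT / "pool_preference.png")

n_pos = sum(r.tai_alt > r.tai_host for r in pair_rows)
print(f"phage/host pairs: {len(pair_rows)}; self-pool tAI higher in {n_pos}")
print(f"signed-rank W={sr.statistic:.1f}, n={sr.n_effective}, "
      f"two-sided p={sr.p:.3g} ({sr.method})")
for r in sat_rows:
    print(f"satellite {r.phage_id}: tAI host={r.tai_host:.3f} "
          f"helper={r.tai_alt:.3f} -> helper pool preferred: {r.tai_alt > r.tai_host}")
print(f"table: {table}")
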