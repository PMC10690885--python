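#!/usr/bin/env python
"""Generate the synthetic phage/host study panel.

Writes 31 phage/host genome pairs plus two satellite trios as annotated
GenBank records, the phage->host pairing manifest, and the tRNA truth table
under results/panel/.  Each phage carries a ~40-gene tRNA set and a major
capsid protein gene whose synonymous codons are adapted toward the phage's
own pool (t = 2); hosts carry larger, GC-rich (71%) repertoires; satellites
carry no tRNA genes and are adapted to their helper's pool.
"""

from pathlib import Path

from poolfit import SyntheticConfig, generate_panel, write_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"

config = SyntheticConfig(seed=20240917, n_pairs=31, n_satellites=2)
panel = generate_panel(config)
write_panel(panel, OUT)

n_sat = sum(1 for e in panel.manifest.entries if e.helper_id)
print(f"wrote {len(panel.genomes)} genomes to {OUT}")
print(f"manifest: {len(panel.manifest.entries)} entries "
      f"({len(panel.manifest.entries) - n_sat} phage/host pairs, {n_sat} satellite trios)")
print(f"conditions: t={config.adaptation_t}, phage pools {config.pool_size_range}, "
      f"host pools {config.host_pool_size_range}, gene {config.gene_length_codons} codons")
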