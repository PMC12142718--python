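"""Find promoter orthologs in a genome and extract their CpG O/E.

Builds a toy genome with two planted promoter copies (one diverged, one on
the minus strand), scans it with the built-in seed-and-extend matcher, and
turns the top hits into the per-promoter O/E feature vector — 0 for the
promoter with no hit, the same encoding used at prediction time.
"""

import tempfile
from pathlib import Path

import numpy as np

from finlife import builtin_scan, promoter_oe_vector
from finlife.synthetic_data import SimulationConfig, mutate_sequence, simulate_promoters

rng = np.random.default_rng(0)
config = SimulationConfig(n_species=1, n_promoters=3, n_causal=0, seed=0)
promoters = simulate_promoters(config)

background = "".join(rng.choice(list("ACGT"), size=800, p=[0.3, 0.2, 0.2, 0.3]))
diverged = mutate_sequence(rng, promoters[0].sequence, 0.10)  # ~90% identity
minus = promoters[1].sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
genome = background + diverged + background + minus + background
# promoters[2] is deliberately absent

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "genome.fa"
    path.write_text(f">contig_1\n{genome}\n")
    hits = builtin_scan(promoters, path, min_identity=70)
    for h in hits:
        print(
            f"{h.promoter_id}: {h.contig_id}:{h.subject_start}-{h.subject_end} "
            f"({h.strand}) identity {h.percent_identity:.1f}%"
        )
    vec = promoter_oe_vector(hits, [p.promoter_id for p in promoters])

print("\nfeature vector (O/E per promoter, 0 = no hit):", np.round(vec, 3))
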