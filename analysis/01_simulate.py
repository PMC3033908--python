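#!/usr/bin/env python
"""Generate the default synthetic chemogenomic dataset.

Draws ~100 family A receptors with BW-labelled alignment positions,
~1664 receptor-ligand pairs (full/partial agonists and antagonists),
promiscuous Gs/Gi/Gq annotations and 30 ligand descriptors, then writes
the TSV/FASTA artifacts the pipeline consumes under results/synthetic/.
"""

import sys
from pathlib import Path

import gpcrmi as g

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main():
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    sim = g.simulate_dataset(g.SimulationConfig(seed=seed))
    paths = g.write_dataset(sim, OUT)
    s = sim.dataset.summary()
    print(f"seed {seed}: wrote {len(paths)} artifacts to {OUT}")
    print(f"receptors: {s['n_receptors']}  pairs: {s['n_pairs']}")
    print(f"pairs by ligand type: {s['pairs_by_ligand_type']}")
    print(f"pairs by G protein:   {s['pairs_by_g_protein']}")
    print(f"planted associations: {len(sim.ground_truth.planted)}")


if __name__ == "__main__":
    main()
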