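"""Synthetic chemogenomic datasets with planted position–descriptor links.

The generator reproduces the statistical shape the analysis assumes: ~100
receptors with aligned positions spanning near-conserved to highly variable
residue distributions, 10–25 ligands per receptor (~1664 receptor–ligand
pairs split ~46/11/43% into full agonists / partial agonists / antagonists),
promiscuous multi-G-protein annotations, and discrete count descriptors
(Poisson) plus two continuous surface areas (normal). Every dataset is a
pure function of its seed.

A *planted association* couples the residue class of a position to a shift
in one descriptor's distribution at the receptor level: all in-scope
ligands of a receptor whose residue falls in the high-probability class
draw the descriptor from a shifted distribution with mixing weight equal
to ``effect_strength``. Everything else is independent, which gives exact
ground truth for null-calibration and recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GAP, AlignmentPositionTable, PositionMap, label_positions
from .data_model import (
    AGONIST_TYPES,
    G_PROTEINS,
    LIGAND_TYPES,
    Dataset,
    LigandRecord,
    ReceptorLigandPair,
    ReceptorRecord,
)
from .descriptors import DescriptorMatrix
from .errors import ConfigError

_MASTER_LABELS = (
    [f"{h}.{x:02d}" for h in range(1, 8) for x in range(38, 61)]
    + [f"Lp2.{x}" for x in range(46, 55)]
    + [f"8.{x}" for x in range(47, 57)]
)

_DISCRETE_BASE = [
    "n_carbon", "n_nitrogen", "n_oxygen", "n_sulfur", "n_halogen",
    "n_rings", "n_aromatic_rings", "n_rotatable_bonds",
    "n_hbond_donors", "n_hbond_acceptors",
]

CONTINUOUS_NAMES = ("molecular_surface_area", "polar_surface_area")

_SCOPES = ("all", "agonist", "antagonist", "Gi", "Gs", "Gq")


def default_position_labels(n: int):
    """Evenly sample n Ballesteros–Weinstein labels across TMH1–7, ECL2, H8."""
    if n > len(_MASTER_LABELS):
        raise ConfigError(f"at most {len(_MASTER_LABELS)} positions supported")
    idx = np.unique(np.round(np.linspace(0, len(_MASTER_LABELS) - 1, n)).astype(int))
    return [_MASTER_LABELS[i] for i in idx]


def default_descriptor_names(n_descriptors: int, n_continuous: int = 2):
    n_discrete = n_descriptors - n_continuous
    if n_discrete < 1:
        raise ConfigError("need at least one discrete descriptor")
    names = list(_DISCRETE_BASE[:n_discrete])
    extra = n_discrete - len(names)
    names += [f"estate_count_{i + 1:02d}" for i in range(max(0, extra))]
    return names + list(CONTINUOUS_NAMES[:n_continuous])


@dataclass(frozen=True)
class PlantedAssociation:
    """One true dependence between a position and a descriptor.

    ``position`` / ``descriptor`` are indices into the generated vocabularies;
    ``scope`` restricts which pairs carry the effect; ``effect_strength`` in
    (0, 1] is the mixing weight of the shifted descriptor distribution.
    """

    position: int
    descriptor: int
    scope: str = "all"
    effect_strength: float = 0.9


@dataclass
class SimulationConfig:
    """Generator settings; the defaults emulate the real dataset's shape."""

    n_receptors: int = 100
    n_positions: int = 60
    ligands_per_receptor: tuple = (10, 25)
    ligand_type_proportions: tuple = (0.46, 0.11, 0.43)  # full/partial/antagonist
    n_descriptors: int = 30
    n_continuous: int = 2
    planted: tuple = ()
    g_annotation_probs: tuple = (0.30, 0.60, 0.10)  # single / pair / triple coupling
    fraction_conserved: float = 0.10
    conserved_concentration: float = 0.05
    concentration_range: tuple = (0.25, 2.5)
    gap_fraction: float = 0.02
    poisson_rate_range: tuple = (0.5, 8.0)
    continuous_params: tuple = ((350.0, 80.0), (90.0, 30.0))  # (mean, sd) per column
    discrete_shift: float = 4.0
    continuous_shift_sd: float = 2.5
    class_mass: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ligand_type_proportions) - 1.0) > 1e-9:
            raise ConfigError("ligand_type_proportions must sum to 1")
        if abs(sum(self.g_annotation_probs) - 1.0) > 1e-9:
            raise ConfigError("g_annotation_probs must sum to 1")
        lo, hi = self.ligands_per_receptor
        if not 1 <= lo <= hi:
            raise ConfigError("ligands_per_receptor must be a non-empty range")
        if self.n_continuous > len(CONTINUOUS_NAMES):
            raise ConfigError("at most two continuous descriptors are defined")
        self.planted = tuple(
            p if isinstance(p, PlantedAssociation) else PlantedAssociation(*p)
            for p in self.planted
        )
        for p in self.planted:
            if not 0 <= p.position < self.n_positions:
                raise ConfigError(f"planted position {p.position} out of range")
            if not 0 <= p.descriptor < self.n_descriptors:
                raise ConfigError(f"planted descriptor {p.descriptor} out of range")
            if not 0.0 < p.effect_strength <= 1.0:
                raise ConfigError(
                    "effect_strength must lie in (0, 1]: a zero-strength planted "
                    "association is indistinguishable from the null"
                )
            if p.scope not in _SCOPES:
                raise ConfigError(f"unknown planted scope {p.scope!r}")
        if not 0.0 <= self.fraction_conserved < 1.0:
            raise ConfigError("fraction_conserved must lie in [0, 1)")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ConfigError("gap_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually planted, in pipeline vocabulary."""

    planted: list  # (position label, descriptor name, scope, effect_strength)
    position_has_dependence: dict  # BW label -> bool


@dataclass
class SimulatedData:
    dataset: Dataset
    alignment: dict
    position_map: PositionMap
    position_table: AlignmentPositionTable
    descriptor_matrix: DescriptorMatrix
    ground_truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Draw one dataset (receptors, alignment, ligands, descriptors) from a config."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    labels = default_position_labels(config.n_positions)
    n_pos, n_rec = len(labels), config.n_receptors
    aa = np.array(list(AMINO_ACIDS))

    # --- per-position residue distributions ---------------------------------
    planted_positions = {p.position for p in config.planted}
    candidates = [i for i in range(n_pos) if i not in planted_positions]
    n_cons = min(int(round(config.fraction_conserved * n_pos)), len(candidates))
    conserved = set(
        rng.choice(candidates, size=n_cons, replace=False).tolist() if n_cons else []
    )
    lo_c, hi_c = config.concentration_range
    residue_probs = np.empty((n_pos, len(aa)))
    residues = np.empty((n_rec, n_pos), dtype="<U1")
    for j in range(n_pos):
        conc = (
            config.conserved_concentration
            if j in conserved
            else float(np.exp(rng.uniform(np.log(lo_c), np.log(hi_c))))
        )
        p = rng.dirichlet(np.full(len(aa), conc))
        residue_probs[j] = p
        residues[:, j] = aa[rng.choice(len(aa), size=n_rec, p=p)]
        if config.gap_fraction > 0:
            residues[rng.random(n_rec) < config.gap_fraction, j] = GAP

    # --- receptors with promiscuous G-protein annotations -------------------
    receptor_ids = [f"R{i + 1:03d}" for i in range(n_rec)]
    n_coupled = rng.choice([1, 2, 3], size=n_rec, p=config.g_annotation_probs)
    receptors = {}
    for i, rid in enumerate(receptor_ids):
        members = rng.choice(3, size=n_coupled[i], replace=False)
        receptors[rid] = ReceptorRecord(rid, frozenset(G_PROTEINS[m] for m in members))

    # --- ligands and pairs ---------------------------------------------------
    lo, hi = config.ligands_per_receptor
    counts = rng.integers(lo, hi + 1, size=n_rec)
    ligand_receptor = np.repeat(np.arange(n_rec), counts)
    n_lig = len(ligand_receptor)
    ligand_ids = [f"L{i + 1:05d}" for i in range(n_lig)]
    type_idx = rng.choice(3, size=n_lig, p=config.ligand_type_proportions)
    ligands = {
        lid: LigandRecord(lid, LIGAND_TYPES[type_idx[i]]) for i, lid in enumerate(ligand_ids)
    }
    pairs = [
        ReceptorLigandPair(receptor_ids[ligand_receptor[i]], lid)
        for i, lid in enumerate(ligand_ids)
    ]
    dataset = Dataset(receptors, ligands, pairs)

    # --- null descriptor values ---------------------------------------------
    desc_names = default_descriptor_names(config.n_descriptors, config.n_continuous)
    n_discrete = config.n_descriptors - config.n_continuous
    rates = rng.uniform(*config.poisson_rate_range, size=n_discrete)
    values = {}
    for d in range(n_discrete):
        values[desc_names[d]] = rng.poisson(rates[d], size=n_lig).astype(float)
    for c in range(config.n_continuous):
        mu, sd = config.continuous_params[c]
        values[desc_names[n_discrete + c]] = rng.normal(mu, sd, size=n_lig)

    # --- plant associations ---------------------------------------------------
    for assoc in config.planted:
        j, d = assoc.position, assoc.descriptor
        # high-probability residue class: top residues holding >= class_mass
        order = np.argsort(residue_probs[j])[::-1]
        cum = np.cumsum(residue_probs[j][order])
        n_class = int(np.searchsorted(cum, config.class_mass) + 1)
        class_aa = set(aa[order[:n_class]])
        rec_in_class = np.array([residues[i, j] in class_aa for i in range(n_rec)])

        lig_scope = np.ones(n_lig, dtype=bool)
        if assoc.scope == "agonist":
            lig_scope = np.array([LIGAND_TYPES[t] in AGONIST_TYPES for t in type_idx])
        elif assoc.scope == "antagonist":
            lig_scope = np.array([LIGAND_TYPES[t] == "antagonist" for t in type_idx])
        elif assoc.scope in G_PROTEINS:
            rec_has_g = np.array(
                [assoc.scope in receptors[r].g_proteins for r in receptor_ids]
            )
            lig_scope = rec_has_g[ligand_receptor]
        affected = rec_in_class[ligand_receptor] & lig_scope
        redraw = affected & (rng.random(n_lig) < assoc.effect_strength)
        n_redraw = int(redraw.sum())
        name = desc_names[d]
        if d < n_discrete:
            values[name][redraw] = rng.poisson(
                rates[d] + config.discrete_shift, size=n_redraw
            ).astype(float)
        else:
            mu, sd = config.continuous_params[d - n_discrete]
            values[name][redraw] = rng.normal(
                mu + config.continuous_shift_sd * sd, sd, size=n_redraw
            )

    df = pd.DataFrame(values, index=pd.Index(ligand_ids, name="ligand_id"))
    kinds = {}
    for i, name in enumerate(desc_names):
        if i < n_discrete:
            df[name] = df[name].astype(int)
            kinds[name] = "discrete"
        else:
            kinds[name] = "continuous"
    descriptor_matrix = DescriptorMatrix(df, kinds)

    # --- alignment artifacts ---------------------------------------------------
    alignment = {rid: "".join(residues[i]) for i, rid in enumerate(receptor_ids)}
    position_map = PositionMap({j: labels[j] for j in range(n_pos)})
    position_table = label_positions(alignment, position_map)

    truth = GroundTruth(
        planted=[
            (labels[p.position], desc_names[p.descriptor], p.scope, p.effect_strength)
            for p in config.planted
        ],
        position_has_dependence={
            labels[j]: (j in planted_positions) for j in range(n_pos)
        },
    )
    return SimulatedData(
        dataset, alignment, position_map, position_table, descriptor_matrix, truth, config
    )


def expected_counts(config: SimulationConfig) -> dict:
    """Analytic expectations under a config, for test assertions."""
    lo, hi = config.ligands_per_receptor
    pairs = config.n_receptors * (lo + hi) / 2.0
    p1, p2, p3 = config.g_annotation_probs
    p_g = p1 / 3.0 + p2 * 2.0 / 3.0 + p3  # P(a given subtype is annotated)
    return {
        "expected_pairs": pairs,
        "expected_by_type": {
            t: pairs * w for t, w in zip(LIGAND_TYPES, config.ligand_type_proportions)
        },
        "expected_agonist_subset": pairs * sum(config.ligand_type_proportions[:2]),
        "expected_antagonist_subset": pairs * config.ligand_type_proportions[2],
        "expected_g_subset": {g: pairs * p_g for g in G_PROTEINS},
    }


def write_dataset(sim: SimulatedData, out_dir) -> dict:
    """Write a simulated dataset in the exact formats the pipeline reads.

    Emits alignment FASTA, position-map TSV, receptor/ligand/pair TSVs, the
    descriptor TSV and a ground-truth JSON; returns the path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "alignment": "alignment.fasta",
        "position_map": "position_map.tsv",
        "receptors": "receptors.tsv",
        "ligands": "ligands.tsv",
        "pairs": "pairs.tsv",
        "descriptors": "descriptors.tsv",
        "ground_truth": "ground_truth.json",
    }.items()}

    with open(paths["alignment"], "w") as fh:
        for rid, seq in sim.alignment.items():
            fh.write(f">{rid}\n{seq}\n")

    with open(paths["position_map"], "w") as fh:
        fh.write("column_index\tbw_label\n")
        for col in sorted(sim.position_map.entries):
            fh.write(f"{col}\t{sim.position_map.entries[col]}\n")

    pd.DataFrame(
        {
            "receptor_id": list(sim.dataset.receptors),
            "g_proteins": [
                ";".join(g for g in G_PROTEINS if g in r.g_proteins)
                for r in sim.dataset.receptors.values()
            ],
        }
    ).to_csv(paths["receptors"], sep="\t", index=False)

    pd.DataFrame(
        {
            "ligand_id": list(sim.dataset.ligands),
            "ligand_type": [l.ligand_type for l in sim.dataset.ligands.values()],
        }
    ).to_csv(paths["ligands"], sep="\t", index=False)

    pd.DataFrame(
        {
            "receptor_id": [p.receptor_id for p in sim.dataset.pairs],
            "ligand_id": [p.ligand_id for p in sim.dataset.pairs],
        }
    ).to_csv(paths["pairs"], sep="\t", index=False)

    # %.17g round-trips float64 exactly through the text format
    sim.descriptor_matrix.values.to_csv(paths["descriptors"], sep="\t", float_format="%.17g")

    truth = {
        "planted": [list(t) for t in sim.ground_truth.planted],
        "position_has_dependence": sim.ground_truth.position_has_dependence,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(sim.config).items()
        },
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True, default=list) + "\n")
    return paths
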