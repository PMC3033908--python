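"""Receptors, ligands, receptor–ligand pairs and the five analysis subsets.

The unit of observation throughout the pipeline is a *receptor–ligand pair*:
a receptor (with its G-protein coupling annotation) matched to one ligand
(with its pharmacological effect class). Pairs are partitioned by ligand
effect into agonist/antagonist subsets and grouped — with overlap, because
many receptors couple promiscuously — into Gs/Gi/Gq subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError

G_PROTEINS = ("Gs", "Gi", "Gq")

#: Effect classes retained for analysis. Inverse agonists and allosteric
#: modulators are excluded by design and rejected at load time.
LIGAND_TYPES = ("full_agonist", "partial_agonist", "antagonist")

SUBSET_NAMES = ("agonist", "antagonist", "Gi", "Gs", "Gq")

AGONIST_TYPES = frozenset({"full_agonist", "partial_agonist"})


@dataclass(frozen=True)
class ReceptorRecord:
    """One receptor with its G-protein coupling preference annotation."""

    receptor_id: str
    g_proteins: frozenset

    def __post_init__(self):
        if not self.g_proteins:
            raise ValidationError(
                f"receptor {self.receptor_id!r}: empty G-protein annotation"
            )
        bad = set(self.g_proteins) - set(G_PROTEINS)
        if bad:
            raise ValidationError(
                f"receptor {self.receptor_id!r}: unknown G proteins {sorted(bad)}"
            )


@dataclass(frozen=True)
class LigandRecord:
    """One ligand with its effect class and optional 2D structure."""

    ligand_id: str
    ligand_type: str
    smiles: str | None = None

    def __post_init__(self):
        if self.ligand_type not in LIGAND_TYPES:
            raise ValidationError(
                f"ligand {self.ligand_id!r}: ligand_type {self.ligand_type!r} "
                f"not one of {LIGAND_TYPES} (inverse agonists and allosteric "
                "modulators are excluded from this analysis)"
            )


@dataclass(frozen=True)
class ReceptorLigandPair:
    """One statistical observation: a receptor matched with one of its ligands."""

    receptor_id: str
    ligand_id: str


@dataclass
class AnalysisSubset:
    """A named slice of the pair set (agonist, antagonist, Gi, Gs or Gq)."""

    name: str
    pairs: list = field(default_factory=list)

    def __len__(self):
        return len(self.pairs)


@dataclass
class Dataset:
    """Validated receptors, ligands and pairs with resolved cross-references."""

    receptors: dict
    ligands: dict
    pairs: list

    def summary(self) -> dict:
        """Counts per ligand effect class and per G-protein annotation."""
        by_type = {t: 0 for t in LIGAND_TYPES}
        for p in self.pairs:
            by_type[self.ligands[p.ligand_id].ligand_type] += 1
        by_g = {g: 0 for g in G_PROTEINS}
        for p in self.pairs:
            for g in self.receptors[p.receptor_id].g_proteins:
                by_g[g] += 1
        return {
            "n_receptors": len(self.receptors),
            "n_ligands": len(self.ligands),
            "n_pairs": len(self.pairs),
            "pairs_by_ligand_type": by_type,
            "pairs_by_g_protein": by_g,
        }


def _normalize_ligand_type(raw: str) -> str:
    return str(raw).strip().lower().replace(" ", "_").replace("-", "_")


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str).fillna("")


def load_pairs(receptor_table, ligand_table, pair_table) -> Dataset:
    """Load and validate the three input tables into a :class:`Dataset`.

    Receptor table needs ``receptor_id`` and ``g_proteins`` (semicolon-
    separated subset of ``Gs;Gi;Gq``); ligand table needs ``ligand_id`` and
    ``ligand_type`` (optionally ``smiles``); pair table needs ``receptor_id``
    and ``ligand_id``. Duplicate pairs are collapsed with a warning so that
    each (receptor, ligand) combination counts as one observation.
    """
    rec_df = _read_table(receptor_table)
    lig_df = _read_table(ligand_table)
    pair_df = _read_table(pair_table)

    _require_columns(rec_df, ["receptor_id", "g_proteins"], "receptor table")
    _require_columns(lig_df, ["ligand_id", "ligand_type"], "ligand table")
    _require_columns(pair_df, ["receptor_id", "ligand_id"], "pair table")

    receptors = {}
    for _, row in rec_df.iterrows():
        rid = row["receptor_id"].strip()
        if rid in receptors:
            raise ValidationError(f"duplicate receptor_id {rid!r}")
        gps = frozenset(g.strip() for g in row["g_proteins"].split(";") if g.strip())
        receptors[rid] = ReceptorRecord(rid, gps)

    ligands = {}
    for _, row in lig_df.iterrows():
        lid = row["ligand_id"].strip()
        if lid in ligands:
            raise ValidationError(f"duplicate ligand_id {lid!r}")
        smiles = row.get("smiles", "") or None
        ligands[lid] = LigandRecord(lid, _normalize_ligand_type(row["ligand_type"]), smiles)

    pairs, seen, n_dup = [], set(), 0
    for _, row in pair_df.iterrows():
        rid, lid = row["receptor_id"].strip(), row["ligand_id"].strip()
        if rid not in receptors:
            raise ReferentialError(f"pair references unknown receptor_id {rid!r}")
        if lid not in ligands:
            raise ReferentialError(f"pair references unknown ligand_id {lid!r}")
        key = (rid, lid)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        pairs.append(ReceptorLigandPair(rid, lid))
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate receptor-ligand pair(s)")

    return Dataset(receptors, ligands, pairs)


def build_subset(
    dataset: Dataset,
    name: str,
    *,
    agonist_includes_partial: bool = True,
    g_subset_agonists_only: bool = False,
) -> AnalysisSubset:
    """Build one of the five analysis subsets.

    ``agonist`` collects pairs whose ligand is a full or partial agonist
    (full only when ``agonist_includes_partial`` is False, in which case
    partial agonists can be analysed separately via the extra subset name
    ``partial_agonist``); ``antagonist`` collects antagonist pairs. A
    G-protein subset collects every pair whose receptor carries that
    coupling annotation — all ligand effects by default, agonists only when
    ``g_subset_agonists_only`` is set.
    """
    allowed = set(SUBSET_NAMES) | {"partial_agonist", "full_agonist"}
    if name not in allowed:
        raise ValidationError(f"unknown subset name {name!r}; expected one of {sorted(allowed)}")

    def ltype(p):
        return dataset.ligands[p.ligand_id].ligand_type

    if name == "agonist":
        keep = AGONIST_TYPES if agonist_includes_partial else {"full_agonist"}
        pairs = [p for p in dataset.pairs if ltype(p) in keep]
    elif name == "full_agonist":
        pairs = [p for p in dataset.pairs if ltype(p) == "full_agonist"]
    elif name == "partial_agonist":
        pairs = [p for p in dataset.pairs if ltype(p) == "partial_agonist"]
    elif name == "antagonist":
        pairs = [p for p in dataset.pairs if ltype(p) == "antagonist"]
    else:  # Gi / Gs / Gq
        pairs = [
            p
            for p in dataset.pairs
            if name in dataset.receptors[p.receptor_id].g_proteins
            and (not g_subset_agonists_only or ltype(p) in AGONIST_TYPES)
        ]
    if not pairs:
        warnings.warn(f"subset {name!r} is empty")
    return AnalysisSubset(name, pairs)
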