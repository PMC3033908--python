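"""Ligand descriptor matrices and discretization for histogram MI.

The descriptor vocabulary is deliberately discrete and countable (element
counts, H-bond donor/acceptor counts, ring and rotatable-bond counts,
atom-type counts); the two exceptions are the molecular surface area and
the polar surface area, which are continuous and must be binned before
they can enter the histogram estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

#: Descriptor names treated as continuous unless configured otherwise.
DEFAULT_CONTINUOUS = ("molecular_surface_area", "polar_surface_area")


@dataclass
class DescriptorMatrix:
    """Ligand × descriptor value matrix with per-descriptor kind flags.

    ``values`` is a DataFrame indexed by ligand_id; ``kinds`` maps each
    descriptor name to ``'discrete'`` (integer counts) or ``'continuous'``.
    """

    values: pd.DataFrame
    kinds: dict

    def __post_init__(self):
        if set(self.kinds) != set(self.values.columns):
            raise ValidationError("kind flags do not cover exactly the descriptor columns")
        bad = {k: v for k, v in self.kinds.items() if v not in {"discrete", "continuous"}}
        if bad:
            raise ValidationError(f"illegal kind flag(s): {bad}")

    @property
    def ligand_ids(self):
        return list(self.values.index)

    @property
    def descriptor_names(self):
        return list(self.values.columns)

    def column(self, name: str, ligand_ids=None) -> np.ndarray:
        sub = self.values[name] if ligand_ids is None else self.values[name].loc[ligand_ids]
        return sub.to_numpy()


def load_descriptor_table(file, continuous=DEFAULT_CONTINUOUS) -> DescriptorMatrix:
    """Load a TSV/CSV descriptor table keyed by ``ligand_id``.

    Columns named in ``continuous`` are flagged continuous; every other
    column must be integer-valued. Missing cells and fractional values in
    count columns are validation errors.
    """
    path = Path(file)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "ligand_id" not in df.columns:
        raise ValidationError("descriptor table missing 'ligand_id' column")
    df = df.set_index("ligand_id")
    if df.index.duplicated().any():
        raise ValidationError("duplicate ligand_id in descriptor table")
    if df.isna().any().any():
        cols = list(df.columns[df.isna().any()])
        raise ValidationError(f"missing cell(s) in descriptor column(s) {cols}")
    kinds = {}
    for name in df.columns:
        if name in continuous:
            kinds[name] = "continuous"
            df[name] = df[name].astype(float)
        else:
            vals = df[name].astype(float)
            if not np.all(vals == np.round(vals)):
                raise ValidationError(
                    f"descriptor {name!r} is flagged discrete but holds non-integer values"
                )
            df[name] = vals.astype(int)
            kinds[name] = "discrete"
    return DescriptorMatrix(df, kinds)


@dataclass
class DiscretizationScheme:
    """How one descriptor column becomes categories.

    ``identity`` (discrete counts only) keeps each integer as its own
    category. ``equal_width`` bins a continuous column into ``n_bins``
    left-closed bins over [min, max], the last bin right-closed.
    """

    method: str
    n_bins: int | None = None
    bin_edges: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in {"identity", "equal_width"}:
            raise ConfigError(f"unknown discretization method {self.method!r}")
        if self.method == "equal_width":
            if self.n_bins is None or self.n_bins < 1:
                raise ConfigError("equal_width requires n_bins >= 1")
        if self.bin_edges is not None and np.any(np.diff(self.bin_edges) <= 0):
            raise ConfigError("bin_edges must be strictly increasing")


def sturges_bins(k: int) -> int:
    """Default bin count for a continuous column: max(2, floor(1 + log2 K))."""
    if k < 1:
        raise ValidationError("sample size must be positive")
    return max(2, int(math.floor(1 + math.log2(k))))


def discretize(column, scheme: DiscretizationScheme) -> np.ndarray:
    """Map a value vector to integer categories under a scheme.

    Downstream MI is invariant to the category labels themselves; only the
    induced partition matters.
    """
    values = np.asarray(column)
    if values.size == 0:
        raise ValidationError("cannot discretize an empty column")
    if scheme.method == "identity":
        as_float = values.astype(float)
        if not np.all(as_float == np.round(as_float)):
            raise ValidationError("identity discretization requires integer values")
        return as_float.astype(int)
    values = values.astype(float)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        warnings.warn("constant continuous column: single category")
        return np.zeros(values.shape, dtype=int)
    edges = (
        scheme.bin_edges
        if scheme.bin_edges is not None
        else np.linspace(lo, hi, scheme.n_bins + 1)
    )
    n_bins = len(edges) - 1
    # left-closed bins [e_k, e_{k+1}); clip puts the maximum into the last bin
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, n_bins - 1).astype(int)


# ---------------------------------------------------------------------------
# Optional 2D-structure descriptor calculator (RDKit backend)
# ---------------------------------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")


def compute_descriptors(structures, continuous=DEFAULT_CONTINUOUS) -> DescriptorMatrix:
    """Compute a descriptor matrix from 2D structures (``{id: SMILES}``).

    Emits per-element atom counts, H-bond donor/acceptor counts, ring and
    rotatable-bond counts, electro-topological state atom-type counts, and
    the two continuous surface areas (Labute approximate surface area and
    topological polar surface area). Unparsable structures are skipped with
    a warning. Requires the optional ``rdkit`` dependency.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors
        from rdkit.Chem.EState import AtomTypes as EStateAtomTypes
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ConfigError("descriptor computation requires the rdkit backend") from exc

    rows = {}
    for lid, smiles in structures.items():
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            warnings.warn(f"unparsable structure for {lid!r}; row skipped")
            continue
        row = {}
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        for el in _ELEMENTS:
            row[f"n_{el}"] = symbols.count(el)
        row["n_hbond_donors"] = Lipinski.NumHDonors(mol)
        row["n_hbond_acceptors"] = Lipinski.NumHAcceptors(mol)
        row["n_rings"] = rdMolDescriptors.CalcNumRings(mol)
        row["n_aromatic_rings"] = rdMolDescriptors.CalcNumAromaticRings(mol)
        row["n_rotatable_bonds"] = rdMolDescriptors.CalcNumRotatableBonds(mol)
        # E-state atom-type counts
        types = EStateAtomTypes.TypeAtoms(mol)
        tally = {}
        for atom_types in types:
            for t in atom_types:
                tally[t] = tally.get(t, 0) + 1
        for t, c in sorted(tally.items()):
            row[f"estate_{t}"] = c
        row["molecular_surface_area"] = float(Descriptors.LabuteASA(mol))
        row["polar_surface_area"] = float(Descriptors.TPSA(mol))
        rows[lid] = row
    if not rows:
        raise ValidationError("no parsable structures")
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    df.index.name = "ligand_id"
    kinds = {}
    for name in df.columns:
        if name in continuous:
            kinds[name] = "continuous"
            df[name] = df[name].astype(float)
        else:
            kinds[name] = "discrete"
            df[name] = df[name].astype(int)
    return DescriptorMatrix(df, kinds)
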