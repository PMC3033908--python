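"""Scanning, hotspot selection and position classification.

A *scan* computes the corrected MI and its surrogate significance for every
eligible (alignment position, descriptor) pair of one analysis subset. The
*hotspots* of a subset are the top 0.5% of MI values that additionally pass
the significance test (S above the t-quantile threshold). Hotspot positions
are then classified by which subsets they light up in: agonist- vs
antagonist-selective (or both), and single / pair / triple G-protein
coupling selectivity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import GAP, AlignmentPositionTable
from .config import ScanConfig
from .data_model import AnalysisSubset, Dataset, build_subset
from .descriptors import DescriptorMatrix, DiscretizationScheme, discretize, sturges_bins
from .errors import InsufficientSample
from .mi import MIResult, PairedSample, corrected_mi
from .significance import (
    SignificanceResult,
    critical_value,
    generate_surrogates,
    lilliefors_test,
    test_statistic,
)


@dataclass
class ScanEntry:
    """One analyzed (position, descriptor) pair of a subset scan."""

    position: str
    descriptor: str
    mi: MIResult
    sig: SignificanceResult | None  # None when the surrogate ensemble is degenerate
    n_dropped_gaps: int = 0


@dataclass
class ScanResult:
    """All entries of one subset scan, ranked by corrected MI (descending)."""

    subset_name: str
    entries: list
    skipped: list  # (position, descriptor, reason)
    threshold: float
    n_pairs: int
    config: ScanConfig = field(repr=False, default=None)


def _sort_key(entry: ScanEntry):
    s = entry.sig.s if entry.sig is not None else -math.inf
    return (-entry.mi.i_corrected, -s, entry.position, entry.descriptor)


def _descriptor_categories(matrix: DescriptorMatrix, ligand_ids, config: ScanConfig):
    """Categorical codes per descriptor, in subset pair order."""
    k = len(ligand_ids)
    out = {}
    for name in matrix.descriptor_names:
        values = matrix.column(name, ligand_ids)
        if matrix.kinds[name] == "continuous":
            n_bins = config.continuous_bins or sturges_bins(k)
            scheme = DiscretizationScheme("equal_width", n_bins=n_bins)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant columns downgrade to one bin
                out[name] = discretize(values, scheme)
        else:
            out[name] = discretize(values, DiscretizationScheme("identity"))
    return out


def scan_subset(
    subset: AnalysisSubset,
    position_table: AlignmentPositionTable,
    descriptor_matrix: DescriptorMatrix,
    config: ScanConfig | None = None,
    *,
    seed: int | None = None,
    stream: int = 0,
) -> ScanResult:
    """Corrected MI + surrogate significance for every eligible pair.

    Deterministic: the surrogate RNG for test (i, j) is seeded from
    ``(seed, stream, i, j)`` (or ``(seed, stream, i)`` shared across the
    row in whole-row permutation mode), so any single test can be
    reproduced in isolation.
    """
    config = config or ScanConfig()
    if seed is None:
        seed = config.master_seed
    if len(subset) == 0:
        warnings.warn(f"subset {subset.name!r}: nothing to scan")
        return ScanResult(subset.name, [], [], critical_value(config.alpha, config.n_surrogates), 0, config)

    pair_rows = position_table.receptor_rows([p.receptor_id for p in subset.pairs])
    ligand_ids = [p.ligand_id for p in subset.pairs]
    y_codes = _descriptor_categories(descriptor_matrix, ligand_ids, config)
    names = descriptor_matrix.descriptor_names
    threshold = critical_value(config.alpha, config.n_surrogates)

    entries, skipped = [], []
    for pi, position in enumerate(position_table.labels):
        symbols = position_table.column(position)[pair_rows]
        if config.gap_policy == "drop":
            mask = symbols != GAP
        else:
            mask = np.ones(len(symbols), dtype=bool)
        n_dropped = int(len(symbols) - mask.sum())
        x = symbols[mask]
        if len(x) < config.k_min:
            skipped.extend((position, d, "insufficient_sample") for d in names)
            continue
        shared_perms = None
        if config.permutation_mode == "whole_row":
            rng = np.random.default_rng(np.random.SeedSequence((seed, stream, pi)))
            shared_perms = rng.permuted(
                np.tile(np.arange(len(x), dtype=np.intp), (config.n_surrogates, 1)),
                axis=1,
            )
        for di, name in enumerate(names):
            y = y_codes[name][mask]
            sample = PairedSample(x, y)
            try:
                mi = corrected_mi(sample, k_min=config.k_min, gap_policy="keep")
            except InsufficientSample:
                skipped.append((position, name, "insufficient_sample"))
                continue
            if config.permutation_mode == "whole_row":
                ensemble = generate_surrogates(
                    sample, config.n_surrogates, permutations=shared_perms,
                    gap_policy="keep",
                )
            else:
                rng = np.random.default_rng(np.random.SeedSequence((seed, stream, pi, di)))
                ensemble = generate_surrogates(
                    sample, config.n_surrogates, rng=rng, gap_policy="keep"
                )
            if ensemble.degenerate:
                sig = None  # conserved position or constant descriptor: S undefined
            else:
                s = test_statistic(mi, ensemble)
                lf = lilliefors_test(ensemble.mi_values, config.lilliefors_alpha)
                sig = SignificanceResult(
                    s=s,
                    threshold=threshold,
                    reject_null=bool(s > threshold),
                    alpha=config.alpha,
                    surrogate_mean=ensemble.mean_mi,
                    surrogate_sd=ensemble.sd_mi,
                    lilliefors_stat=lf.statistic,
                    lilliefors_reject=lf.reject,
                )
            entries.append(ScanEntry(position, name, mi, sig, n_dropped))
    entries.sort(key=_sort_key)
    return ScanResult(subset.name, entries, skipped, threshold, len(subset), config)


def select_top_fraction(scan: ScanResult, fraction: float = 0.005):
    """Hotspot selection: top fraction of MI values, then significance.

    Returns ``(top_entries, hotspot_entries)``: the ceil(fraction × n)
    highest-I_corrected entries (ties broken deterministically by higher S,
    then position, then descriptor), and their subset that passes
    S > threshold. Both lists are exposed so either filter order can be
    audited.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not scan.entries:
        return [], []
    m = math.ceil(fraction * len(scan.entries))
    top = scan.entries[:m]  # entries are already sorted with the tie-break
    hot = [e for e in top if e.sig is not None and e.sig.reject_null]
    return top, hot


def _counts_by_position(hotspots):
    counts = {}
    for e in hotspots:
        counts[e.position] = counts.get(e.position, 0) + 1
    return counts


def classify_position_effects(agonist_hotspots, antagonist_hotspots) -> pd.DataFrame:
    """Per-position effect selectivity from the two effect-subset hotspot sets.

    ``n_agonist`` / ``n_antagonist`` count the significantly correlated
    descriptors per subset; positions in neither set are omitted.
    """
    ago = _counts_by_position(agonist_hotspots)
    ant = _counts_by_position(antagonist_hotspots)
    rows = []
    for pos in sorted(set(ago) | set(ant)):
        a, b = ago.get(pos, 0), ant.get(pos, 0)
        if a and b:
            cls = "both"
        elif a:
            cls = "agonist_selective"
        else:
            cls = "antagonist_selective"
        rows.append({"position": pos, "effect_class": cls, "n_agonist": a, "n_antagonist": b})
    return pd.DataFrame(rows, columns=["position", "effect_class", "n_agonist", "n_antagonist"])


def classify_gprotein_selectivity(gi_hotspots, gq_hotspots, gs_hotspots) -> pd.DataFrame:
    """Per-position G-protein selectivity class with per-subtype counts.

    Classes: a single subtype (``Gi``/``Gq``/``Gs``), one of the three pairs
    (``Gi/Gq``, ``Gi/Gs``, ``Gs/Gq``), or ``triple``.
    """
    counts = {
        "Gi": _counts_by_position(gi_hotspots),
        "Gq": _counts_by_position(gq_hotspots),
        "Gs": _counts_by_position(gs_hotspots),
    }
    rows = []
    all_pos = sorted(set().union(*counts.values()))
    for pos in all_pos:
        members = [g for g in ("Gi", "Gq", "Gs") if pos in counts[g]]
        if len(members) == 3:
            cls = "triple"
        elif len(members) == 2:
            cls = "/".join(members)
        else:
            cls = members[0]
        rows.append(
            {
                "position": pos,
                "g_class": cls,
                "n_Gi": counts["Gi"].get(pos, 0),
                "n_Gq": counts["Gq"].get(pos, 0),
                "n_Gs": counts["Gs"].get(pos, 0),
            }
        )
    return pd.DataFrame(rows, columns=["position", "g_class", "n_Gi", "n_Gq", "n_Gs"])


def descriptor_frequency(hotspots_by_subset: dict) -> pd.DataFrame:
    """Per-descriptor hotspot occurrence counts per subset, sorted by total.

    When both effect subsets are present, descriptors are additionally
    flagged ``shared`` / ``agonist_only`` / ``antagonist_only``. Descriptors
    absent from all hotspot sets are omitted.
    """
    names = sorted({e.descriptor for hs in hotspots_by_subset.values() for e in hs})
    rows = []
    for d in names:
        row = {"descriptor": d}
        for subset, hs in hotspots_by_subset.items():
            row[f"n_{subset}"] = sum(1 for e in hs if e.descriptor == d)
        rows.append(row)
    cols = ["descriptor"] + [f"n_{s}" for s in hotspots_by_subset]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        if {"agonist", "antagonist"} <= set(hotspots_by_subset):
            df["occurrence"] = pd.Series(dtype=str)
        return df
    df["total"] = df[[c for c in cols if c != "descriptor"]].sum(axis=1)
    df = df.sort_values(["total", "descriptor"], ascending=[False, True]).drop(columns="total")
    if {"agonist", "antagonist"} <= set(hotspots_by_subset):
        def flag(r):
            a, b = r["n_agonist"] > 0, r["n_antagonist"] > 0
            return "shared" if a and b else ("agonist_only" if a else "antagonist_only")
        df["occurrence"] = df.apply(flag, axis=1)
    return df.reset_index(drop=True)


@dataclass
class HotspotReport:
    """Bundle of scans, hotspot lists and classifications for one run."""

    scans: dict
    top: dict
    hotspots: dict
    effect_classes: pd.DataFrame
    g_classes: pd.DataFrame
    effect_descriptor_freq: pd.DataFrame
    g_descriptor_freq: pd.DataFrame
    config: ScanConfig
    seed: int


def run_pipeline(
    dataset: Dataset,
    position_table: AlignmentPositionTable,
    descriptor_matrix: DescriptorMatrix,
    config: ScanConfig | None = None,
    subsets=("agonist", "antagonist", "Gi", "Gs", "Gq"),
) -> HotspotReport:
    """Full analysis: build subsets, scan, select hotspots, classify."""
    config = config or ScanConfig()
    scans, top, hotspots = {}, {}, {}
    for si, name in enumerate(subsets):
        subset = build_subset(
            dataset,
            name,
            agonist_includes_partial=config.agonist_includes_partial,
            g_subset_agonists_only=config.g_subset_agonists_only,
        )
        scan = scan_subset(
            subset, position_table, descriptor_matrix, config,
            seed=config.master_seed, stream=si,
        )
        scans[name] = scan
        top[name], hotspots[name] = select_top_fraction(scan, config.top_fraction)

    empty = pd.DataFrame()
    effect_classes = (
        classify_position_effects(hotspots["agonist"], hotspots["antagonist"])
        if {"agonist", "antagonist"} <= set(hotspots)
        else empty
    )
    g_classes = (
        classify_gprotein_selectivity(hotspots["Gi"], hotspots["Gq"], hotspots["Gs"])
        if {"Gi", "Gq", "Gs"} <= set(hotspots)
        else empty
    )
    effect_freq = (
        descriptor_frequency({k: hotspots[k] for k in ("agonist", "antagonist") if k in hotspots})
        if {"agonist", "antagonist"} <= set(hotspots)
        else empty
    )
    g_freq = (
        descriptor_frequency({k: hotspots[k] for k in ("Gi", "Gq", "Gs") if k in hotspots})
        if {"Gi", "Gq", "Gs"} <= set(hotspots)
        else empty
    )
    return HotspotReport(
        scans, top, hotspots, effect_classes, g_classes, effect_freq, g_freq,
        config, config.master_seed,
    )


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def _scan_frame(report: HotspotReport) -> pd.DataFrame:
    rows = []
    for name, scan in report.scans.items():
        in_top = {(e.position, e.descriptor) for e in report.top.get(name, [])}
        in_hot = {(e.position, e.descriptor) for e in report.hotspots.get(name, [])}
        for e in scan.entries:
            rows.append(
                {
                    "subset": name,
                    "position": e.position,
                    "descriptor": e.descriptor,
                    "n": e.mi.n,
                    "n_dropped_gaps": e.n_dropped_gaps,
                    "h_x": e.mi.h_x,
                    "h_y": e.mi.h_y,
                    "h_xy": e.mi.h_xy,
                    "i_raw": e.mi.i_raw,
                    "bias": e.mi.bias,
                    "i_corrected": e.mi.i_corrected,
                    "b_x": e.mi.b_x,
                    "b_y": e.mi.b_y,
                    "b_xy": e.mi.b_xy,
                    "surrogate_mean": e.sig.surrogate_mean if e.sig else "",
                    "surrogate_sd": e.sig.surrogate_sd if e.sig else "",
                    "s": e.sig.s if e.sig else "",
                    "threshold": scan.threshold,
                    "significant": bool(e.sig.reject_null) if e.sig else False,
                    "lilliefors_reject": e.sig.lilliefors_reject if e.sig else "",
                    "in_top_fraction": (e.position, e.descriptor) in in_top,
                    "is_hotspot": (e.position, e.descriptor) in in_hot,
                }
            )
        for pos, desc, reason in scan.skipped:
            rows.append({"subset": name, "position": pos, "descriptor": desc, "skipped": reason})
    return pd.DataFrame(rows)


def write_reports(report: HotspotReport, out_dir, attribute_file: bool = False) -> list:
    """Write the run's CSV tables and JSON summary; returns written paths.

    Produces ``scan.csv`` (every analyzed pair, with both the top-fraction
    and significance filters flagged so either reading of the selection
    order can be audited), ``hotspots.csv``, ``position_classes.csv``,
    ``descriptor_frequencies.csv`` and ``run_summary.json``; optionally a
    per-position attribute file for molecular-viewer coloring. Output is
    byte-deterministic for identical (inputs, config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    scan_df = _scan_frame(report)
    p = out / "scan.csv"
    scan_df.to_csv(p, index=False, float_format=_FLOAT_FMT)
    written.append(p)

    hot_rows = [
        {
            "subset": name,
            "position": e.position,
            "descriptor": e.descriptor,
            "i_corrected": e.mi.i_corrected,
            "s": e.sig.s,
            "n": e.mi.n,
        }
        for name, entries in report.hotspots.items()
        for e in entries
    ]
    hot_df = pd.DataFrame(
        hot_rows, columns=["subset", "position", "descriptor", "i_corrected", "s", "n"]
    )
    p = out / "hotspots.csv"
    hot_df.to_csv(p, index=False, float_format=_FLOAT_FMT)
    written.append(p)

    eff = report.effect_classes
    gcl = report.g_classes
    if eff.empty and gcl.empty:
        classes = pd.DataFrame(
            columns=["position", "effect_class", "n_agonist", "n_antagonist",
                     "g_class", "n_Gi", "n_Gq", "n_Gs"]
        )
    elif eff.empty:
        classes = gcl
    elif gcl.empty:
        classes = eff
    else:
        classes = pd.merge(eff, gcl, on="position", how="outer").sort_values("position")
        for c in ("n_agonist", "n_antagonist", "n_Gi", "n_Gq", "n_Gs"):
            classes[c] = classes[c].fillna(0).astype(int)
        for c in ("effect_class", "g_class"):
            classes[c] = classes[c].fillna("none")
    p = out / "position_classes.csv"
    classes.to_csv(p, index=False, float_format=_FLOAT_FMT)
    written.append(p)

    freq_frames = []
    if not report.effect_descriptor_freq.empty:
        freq_frames.append(report.effect_descriptor_freq.assign(comparison="effect"))
    if not report.g_descriptor_freq.empty:
        freq_frames.append(report.g_descriptor_freq.assign(comparison="g_protein"))
    freq = (
        pd.concat(freq_frames, ignore_index=True)
        if freq_frames
        else pd.DataFrame(columns=["descriptor", "comparison"])
    )
    p = out / "descriptor_frequencies.csv"
    freq.to_csv(p, index=False, float_format=_FLOAT_FMT)
    written.append(p)

    summary = {
        "config": report.config.to_dict(),
        "seed": report.seed,
        "subsets": {
            name: {
                "n_pairs": scan.n_pairs,
                "n_entries": len(scan.entries),
                "n_skipped": len(scan.skipped),
                "n_top": len(report.top.get(name, [])),
                "n_hotspots": len(report.hotspots.get(name, [])),
            }
            for name, scan in report.scans.items()
        },
    }
    p = out / "run_summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)

    if attribute_file:
        lines = ["position\teffect_class\tg_class"]
        eff_map = dict(zip(eff["position"], eff["effect_class"])) if not eff.empty else {}
        g_map = dict(zip(gcl["position"], gcl["g_class"])) if not gcl.empty else {}
        for pos in sorted(set(eff_map) | set(g_map)):
            lines.append(f"{pos}\t{eff_map.get(pos, 'none')}\t{g_map.get(pos, 'none')}")
        p = out / "position_attributes.tsv"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    return written
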