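"""Allele-balance ploidy and collapsed-assembly diagnostics.

At a biallelic heterozygous site the relative alternative-allele coverage
``rel_alt = alt_depth / (ref_depth + alt_depth)`` estimates the fraction of
genome copies carrying the alternative allele.  Its distribution over many
sites is therefore diagnostic of copy number: a diploid shows a single peak
around 0.50, a triploid two peaks around 0.33 and 0.67, and a tetraploid
three peaks around 0.25, 0.50 and 0.75.  Genuinely diploid genomes whose
assembly collapsed near-identical duplicated regions show the apparent
higher-ploidy pattern in those regions, because reads from both copies pile
onto one assembled sequence.

Mode detection is a deliberately simple histogram peak caller: fixed-width
bins, 3-bin moving-average smoothing, local maxima above a prominence
fraction of the global maximum.  All parameters are exposed and echoed into
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import PpscanError

__all__ = [
    "PloidyCall",
    "PLOIDY_TEMPLATES",
    "load_het_sites",
    "detect_modes",
    "classify_ploidy_pattern",
    "call_ploidy",
    "compare_gene_sets",
]

PLOIDY_TEMPLATES: dict[str, tuple[float, ...]] = {
    "diploid": (0.5,),
    "triploid": (1 / 3, 2 / 3),
    "tetraploid": (0.25, 0.5, 0.75),
}


@dataclass
class PloidyCall:
    """Ploidy pattern call for one unit (scaffold or gene set)."""

    unit: str
    modes: list[float] = field(default_factory=list)
    pattern: str = "unresolved"
    n_sites: int = 0


def _finalize(df: pd.DataFrame, min_mq, min_depth) -> tuple[pd.DataFrame, dict]:
    log = {"n_in": len(df)}
    total = df["ref_depth"] + df["alt_depth"]
    keep = total > min_depth
    if "mq" in df.columns:
        keep &= df["mq"] > min_mq
    df = df.loc[keep].copy()
    df["rel_alt"] = df["alt_depth"] / (df["ref_depth"] + df["alt_depth"])
    # non-het rows (all reads on one allele) carry no allele-balance signal
    het = (df["rel_alt"] > 0) & (df["rel_alt"] < 1)
    log["n_dropped_filters"] = log["n_in"] - int(keep.sum())
    log["n_dropped_homozygous"] = int((~het).sum())
    df = df.loc[het].reset_index(drop=True)
    log["n_retained"] = len(df)
    return df, log


def load_het_sites(
    source,
    min_mq: float = 40.0,
    min_depth: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Load per-site allele depths from a TSV or VCF.

    TSV columns: chrom/scaffold, pos, ref_depth, alt_depth and optionally
    mq.  VCF rows must carry AD-style per-sample allele depths; multiallelic
    records are skipped (counted in the log).  Retains biallelic
    heterozygous sites with MQ > ``min_mq`` (when available) and total
    depth > ``min_depth`` — both strict inequalities.

    Returns ``(table, log)`` where the table has columns
    (scaffold, pos, ref_depth, alt_depth, rel_alt).
    """
    path = Path(source)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        df, log = _read_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t")
        rename = {"chrom": "scaffold", "#chrom": "scaffold", "chr": "scaffold"}
        df = df.rename(columns={c: rename.get(c.lower(), c.lower()) for c in df.columns})
        required = {"scaffold", "pos", "ref_depth", "alt_depth"}
        missing = required - set(df.columns)
        if missing:
            raise PpscanError(
                "het-site table is missing columns: " + ", ".join(sorted(missing))
            )
        log = {}
    df, flog = _finalize(df, min_mq, min_depth)
    return df, {**log, **flog}


def _read_vcf(path: Path) -> tuple[pd.DataFrame, dict]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise PpscanError(
            "reading VCF requires the cyvcf2 extra (pip install ppscan[vcf])"
        ) from exc
    rows = []
    n_multi = n_nodepth = 0
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise PpscanError(
                f"VCF record {rec.CHROM}:{rec.POS} lacks the AD (allelic "
                "depth) FORMAT field"
            )
        ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
        if ref_d < 0 or alt_d < 0:
            n_nodepth += 1
            continue
        mq = rec.INFO.get("MQ")
        rows.append(
            {
                "scaffold": rec.CHROM,
                "pos": rec.POS,
                "ref_depth": ref_d,
                "alt_depth": alt_d,
                **({"mq": float(mq)} if mq is not None else {}),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["scaffold", "pos", "ref_depth", "alt_depth"])
    return df, {"n_multiallelic_skipped": n_multi, "n_missing_depth": n_nodepth}


def detect_modes(
    table: pd.DataFrame,
    bin_width: float = 0.02,
    min_sites: int = 5,
    prominence: float = 0.15,
) -> list[float]:
    """Mode locations of the rel_alt distribution.

    Histogram on (0, 1) with ``bin_width`` bins, smoothed by a 3-bin moving
    average; modes are local maxima of the smoothed curve exceeding
    ``prominence`` x the global maximum, with each mode's location refined
    to the raw-count maximum among the peak bin and its two neighbours
    (smoothing locates peaks robustly but flattens sharp ones by up to one
    bin).  Returns bin centers sorted ascending; an empty list when the
    table has fewer than ``min_sites`` rows (an unresolved call, not an
    error).
    """
    if len(table) < min_sites:
        return []
    rel = table["rel_alt"].to_numpy()
    # bin edges at half-multiples so centers sit on multiples of bin_width
    # (a point mass at 0.5 then yields a mode at exactly 0.5)
    n_bins = int(round(1.0 / bin_width)) + 1
    edges = (np.arange(n_bins + 1) - 0.5) * bin_width
    counts, edges = np.histogram(rel, bins=edges)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peak_floor = prominence * smooth.max()
    centers = np.round((edges[:-1] + edges[1:]) / 2.0, 10)
    modes: set[float] = set()
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        if smooth[i] > left and smooth[i] >= right and smooth[i] >= peak_floor:
            if smooth[i] <= 0:
                continue
            lo, hi = max(i - 1, 0), min(i + 2, len(counts))
            j = lo + int(np.argmax(counts[lo:hi]))
            modes.add(float(centers[j]))
    return sorted(modes)


def classify_ploidy_pattern(
    modes: list[float], tolerance: float = 0.05
) -> str:
    """Match detected modes against the diploid/triploid/tetraploid
    templates {0.5}, {1/3, 2/3}, {1/4, 1/2, 3/4}.

    The winning template must have *every* template mode matched by a
    detected mode within ``tolerance``; among fully matched templates the
    one matching the most modes wins (ties -> unresolved).
    """
    if not modes:
        return "unresolved"
    best, best_n = "unresolved", 0
    tied = False
    for name, template in PLOIDY_TEMPLATES.items():
        matched = [
            any(abs(m - t) <= tolerance for m in modes) for t in template
        ]
        if not all(matched):
            continue
        if len(template) > best_n:
            best, best_n, tied = name, len(template), False
        elif len(template) == best_n:
            tied = True
    if tied:
        return "unresolved"
    return best


def call_ploidy(
    table: pd.DataFrame,
    unit: str = "all",
    bin_width: float = 0.02,
    min_sites: int = 5,
    tolerance: float = 0.05,
    prominence: float = 0.15,
) -> PloidyCall:
    """Detect modes and classify the ploidy pattern of one unit."""
    modes = detect_modes(
        table, bin_width=bin_width, min_sites=min_sites, prominence=prominence
    )
    pattern = (
        classify_ploidy_pattern(modes, tolerance) if modes else "unresolved"
    )
    return PloidyCall(unit=unit, modes=modes, pattern=pattern, n_sites=len(table))


def assign_gene_sets(
    table: pd.DataFrame, gene_sets: dict[str, list[tuple[str, int, int]]]
) -> dict[str, pd.DataFrame]:
    """Split a het-site table by gene-set coordinate lists
    (scaffold, start, end), 1-based inclusive."""
    out = {}
    for name, coords in gene_sets.items():
        mask = np.zeros(len(table), dtype=bool)
        for scaffold, start, end in coords:
            mask |= (
                (table["scaffold"] == scaffold)
                & (table["pos"] >= start)
                & (table["pos"] <= end)
            ).to_numpy()
        out[name] = table.loc[mask].reset_index(drop=True)
    return out


def compare_gene_sets(
    table: pd.DataFrame,
    gene_sets: dict[str, list[tuple[str, int, int]]],
    min_sites: int = 5,
) -> dict:
    """Compare allele-balance spread between gene sets.

    The spread statistic per site is |rel_alt - 0.5|: tetraploid-patterned
    (collapsed) regions put mass near 0.25/0.75 and hence show larger
    spread.  Sets are compared pairwise with a two-sided Mann-Whitney U
    test on the spread; the report orders sets by mean spread.
    """
    subsets = assign_gene_sets(table, gene_sets)
    kept = {}
    skipped = []
    for name, sub in subsets.items():
        if len(sub) >= min_sites:
            kept[name] = sub
        else:
            skipped.append(name)
    spreads = {
        name: (sub["rel_alt"] - 0.5).abs().to_numpy()
        for name, sub in kept.items()
    }
    pairwise = {}
    names = sorted(kept)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            stat = mannwhitneyu(spreads[a], spreads[b], alternative="two-sided")
            pairwise[f"{a}_vs_{b}"] = {
                "U": float(stat.statistic),
                "p_value": float(stat.pvalue),
            }
    return {
        "n_sites": {name: int(len(sub)) for name, sub in kept.items()},
        "mean_spread": {
            name: float(np.mean(sp)) for name, sp in spreads.items()
        },
        "spread_order": sorted(spreads, key=lambda n: float(np.mean(spreads[n]))),
        "pairwise": pairwise,
        "skipped_sets": skipped,
    }
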