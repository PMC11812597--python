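"""GWAS locus definition and comparison with gene-level burden results.

Works purely on summary tables: LD-clumped GWAS hits are merged into large
non-overlapping loci (transitive 1 Mb closure seeded from the most
significant hit), loci are annotated with overlapping genes, and the
resulting rankings are compared with loss-of-function burden-test results —
via power-matched top-locus selection, per-locus minimum-p concordance,
an LD-block-level comparison, and nearest-gene hit counting.

Coordinates are 1-based inclusive throughout (BED input is converted on
read by :mod:`traitspec.tables`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "Locus",
    "group_loci",
    "assign_genes",
    "select_top_locus_genes",
    "overlap_fraction",
    "locus_concordance",
    "ld_block_compare",
    "nearest_gene_hit_counts",
]

GWAS_THRESHOLD = 5e-8
DEFAULT_WINDOW = 1_000_000


@dataclass
class Locus:
    """A merged genomic locus of GWAS hits (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    members: pd.DataFrame = field(repr=False)  # member hits, sorted by position
    min_p: float = np.nan
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must not exceed end")

    @property
    def n_hits(self) -> int:
        return len(self.members)


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    required = {"variant", "chrom", "pos", "pval"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {sorted(missing)}")
    if hits["variant"].duplicated().any():
        dups = hits.loc[hits["variant"].duplicated(), "variant"].tolist()[:5]
        raise ValueError(f"duplicate variant ids in hits table: {dups}")
    if ((hits["pval"] <= 0) | (hits["pval"] > 1)).any():
        raise ValueError("hit p-values must be in (0, 1]")
    if (hits["pos"] < 1).any():
        raise ValueError("hit positions must be >= 1 (1-based)")
    return hits


def group_loci(hits: pd.DataFrame, window: int = DEFAULT_WINDOW) -> list[Locus]:
    """Merge LD-clumped GWAS hits into non-overlapping loci.

    Hits are processed in ascending p-value order (ties broken by
    chromosome then position).  Each locus is seeded with the most
    significant unassigned hit and transitively absorbs every unassigned
    hit within ``window`` of any member, until closure.  Any two hits in
    different loci on the same chromosome end up more than ``window``
    apart, and the result is independent of input row order.
    """
    hits = _validate_hits(hits.copy())
    hits = hits.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    loci: list[Locus] = []
    # per-chromosome arrays of positions sorted ascending, plus assignment mask
    assigned = np.zeros(len(hits), dtype=bool)
    chrom_rows = {c: sub.index.to_numpy() for c, sub in hits.groupby("chrom", sort=False)}
    seed_order = hits.sort_values(
        ["pval", "chrom", "pos"], kind="stable"
    ).index.to_numpy()

    for seed in seed_order:
        if assigned[seed]:
            continue
        chrom = hits.at[seed, "chrom"]
        rows = chrom_rows[chrom]
        live = rows[~assigned[rows]]
        pos = hits.loc[live, "pos"].to_numpy()
        # positions are sorted; the locus is the maximal run of unassigned
        # hits around the seed with consecutive gaps <= window (transitive
        # closure: each next hit joins via its neighbour)
        k = int(np.searchsorted(pos, hits.at[seed, "pos"]))
        lo = k
        while lo > 0 and pos[lo] - pos[lo - 1] <= window:
            lo -= 1
        hi = k
        while hi < len(pos) - 1 and pos[hi + 1] - pos[hi] <= window:
            hi += 1
        member_rows = live[lo:hi + 1]
        assigned[member_rows] = True
        members = hits.loc[member_rows].sort_values("pos", kind="stable")
        loci.append(Locus(
            chrom=chrom,
            start=int(members["pos"].min()),
            end=int(members["pos"].max()),
            members=members.reset_index(drop=True),
            min_p=float(members["pval"].min()),
        ))
    return loci


def assign_genes(loci: list[Locus], genes: pd.DataFrame) -> list[Locus]:
    """Attach to each locus the genes whose interval intersects its span.

    Overlap is inclusive: a gene sharing a single base with the locus span
    is assigned.  Modifies loci in place and returns them.
    """
    for locus in loci:
        sub = genes.loc[genes["chrom"] == locus.chrom]
        hit = (sub["start"] <= locus.end) & (sub["end"] >= locus.start)
        locus.genes = sub.loc[hit, "gene"].tolist()
    return loci


def select_top_locus_genes(
    loci: list[Locus],
    burden: pd.DataFrame,
    burden_threshold: float,
    strict_stop: bool = False,
) -> tuple[set[str], list[Locus]]:
    """Power-matched top-locus gene selection.

    Loci are ranked by minimum GWAS p-value and walked in order: each locus
    contributes all of its burden-significant overlapping genes, or — if it
    has none — its single overlapping gene with the smallest burden
    p-value; loci with no overlapping genes contribute nothing but still
    consume a rank slot.  The walk stops as soon as the number of selected
    genes reaches the genome-wide count of burden-significant genes; the
    final locus is included in full (it may overshoot) unless
    ``strict_stop`` truncates its contribution at the target.

    Returns the selected gene set and the list of top loci consumed.
    """
    burden_p = burden.set_index("gene")["pval"]
    target = int((burden_p < burden_threshold).sum())
    if target == 0:
        warnings.warn("no burden-significant genes; empty selection",
                      RuntimeWarning, stacklevel=2)
        return set(), []
    ranked = sorted(loci, key=lambda loc: (loc.min_p, loc.chrom, loc.start))
    selected: set[str] = set()
    top: list[Locus] = []
    for locus in ranked:
        if len(selected) >= target:
            break
        top.append(locus)
        known = [g for g in locus.genes if g in burden_p.index]
        if not known:
            continue
        sig = [g for g in known if burden_p[g] < burden_threshold]
        contribution = sig if sig else [min(known, key=lambda g: (burden_p[g], g))]
        for g in contribution:
            if strict_stop and len(selected) >= target:
                break
            selected.add(g)
    return selected, top


def overlap_fraction(significant_burden_genes, top_loci: list[Locus]) -> float:
    """Fraction of burden-significant genes contained in any top GWAS locus."""
    sig = set(significant_burden_genes)
    if not sig:
        raise ValueError("overlap fraction undefined: no significant burden genes")
    in_top = set().union(*(set(loc.genes) for loc in top_loci)) if top_loci else set()
    return len(sig & in_top) / len(sig)


def locus_concordance(loci: list[Locus], burden: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Per-locus minimum GWAS vs. minimum burden p-values and their rank correlation.

    Loci without overlapping genes are excluded.  The Spearman correlation
    is computed on ``-log10 p``; with fewer than three informative loci it
    is undefined and returned as ``None``.
    """
    burden_p = burden.set_index("gene")["pval"]
    rows = []
    for i, locus in enumerate(loci):
        known = [g for g in locus.genes if g in burden_p.index]
        if not known:
            continue
        rows.append({
            "locus": i, "chrom": locus.chrom, "start": locus.start, "end": locus.end,
            "min_gwas_p": locus.min_p,
            "min_burden_p": float(burden_p[known].min()),
        })
    table = pd.DataFrame(rows)
    if len(table) < 3:
        return table, None
    rho = spearmanr(-np.log10(table["min_gwas_p"]), -np.log10(table["min_burden_p"])).statistic
    return table, float(rho)


def ld_block_compare(
    blocks: pd.DataFrame,
    gwas_variants: pd.DataFrame,
    burden: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-LD-block minimum GWAS and burden p-values, with duplicate dropping.

    Blocks (1-based inclusive, non-overlapping within chromosome) receive
    the minimum GWAS p-value over contained variants and the minimum
    burden p-value over genes overlapping any part of the block.  Blocks
    with no variants or no overlapping genes are excluded.  When a run of
    genomically consecutive retained blocks shares the identical
    minimum-burden gene (one significant gene spanning them), every block
    in the run is dropped — the conservative reading.
    """
    blocks = blocks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for _, sub in blocks.groupby("chrom", sort=False):
        if (sub["start"].to_numpy()[1:] <= sub["end"].to_numpy()[:-1]).any():
            raise ValueError("LD blocks overlap within a chromosome")
    burden_p = burden.set_index("gene")["pval"]
    rows = []
    for idx, blk in blocks.iterrows():
        vs = gwas_variants.loc[
            (gwas_variants["chrom"] == blk["chrom"])
            & (gwas_variants["pos"] >= blk["start"])
            & (gwas_variants["pos"] <= blk["end"])
        ]
        gs = genes.loc[
            (genes["chrom"] == blk["chrom"])
            & (genes["start"] <= blk["end"])
            & (genes["end"] >= blk["start"])
        ]
        known = [g for g in gs["gene"] if g in burden_p.index]
        if vs.empty or not known:
            continue
        sub_p = burden_p[known]
        min_gene = sub_p.idxmin()
        rows.append({
            "block": idx, "chrom": blk["chrom"], "start": blk["start"], "end": blk["end"],
            "min_gwas_p": float(vs["pval"].min()),
            "min_burden_p": float(sub_p.min()),
            "min_burden_gene": min_gene,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    drop = np.zeros(len(table), dtype=bool)
    for _, sub in table.groupby("chrom", sort=False):
        ii = sub.index.to_numpy()
        run_start = 0
        for j in range(1, len(ii) + 1):
            end_of_run = (
                j == len(ii)
                or table.at[ii[j], "min_burden_gene"] != table.at[ii[run_start], "min_burden_gene"]
            )
            if end_of_run:
                if j - run_start >= 2:
                    drop[ii[run_start:j]] = True
                run_start = j
    return table.loc[~drop].reset_index(drop=True)


def nearest_gene_hit_counts(hits: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Number of GWAS hits assigned to each gene by nearest midpoint.

    Each hit goes to the gene with the closest midpoint on its chromosome;
    equidistant ties resolve to the gene with the smaller start coordinate.
    Hits on chromosomes without genes are left unassigned with a warning.
    Returns a count per gene (zero for genes receiving no hits).
    """
    genes = genes.copy()
    if "midpoint" not in genes.columns:
        genes["midpoint"] = (genes["start"] + genes["end"]) // 2
    counts = pd.Series(0, index=genes["gene"], dtype=int)
    for chrom, sub_hits in hits.groupby("chrom", sort=False):
        sub_genes = genes.loc[genes["chrom"] == chrom]
        if sub_genes.empty:
            warnings.warn(f"no genes on chromosome {chrom}; "
                          f"{len(sub_hits)} hits unassigned", RuntimeWarning, stacklevel=2)
            continue
        # sort by midpoint, then start so the lower-start gene wins exact ties
        sub_genes = sub_genes.sort_values(["midpoint", "start"], kind="stable")
        mids = sub_genes["midpoint"].to_numpy()
        names = sub_genes["gene"].to_numpy()
        starts = sub_genes["start"].to_numpy()
        pos = sub_hits["pos"].to_numpy()
        right = np.searchsorted(mids, pos)
        left = np.clip(right - 1, 0, len(mids) - 1)
        right = np.clip(right, 0, len(mids) - 1)
        d_left = np.abs(pos - mids[left])
        d_right = np.abs(mids[right] - pos)
        tie = d_left == d_right
        choose_left = (d_left < d_right) | (tie & (starts[left] <= starts[right]))
        chosen = np.where(choose_left, left, right)
        assigned = pd.Series(names[chosen]).value_counts()
        counts.loc[assigned.index] += assigned.astype(int)
    return counts
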