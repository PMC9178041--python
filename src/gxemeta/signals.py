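"""Independent signals, associated loci, set overlaps and power.

An *independent signal* is a lead SNP surviving greedy LD clumping of
genome-wide significant variants (take the smallest-p unassigned SNP,
absorb every unassigned SNP within a physical window and above an r-square
threshold, repeat).  An *associated locus* is the union of +/-flank
windows around signals after merging overlaps: an interval of at least
1 Mb harbouring at least one signal.

Positions are 1-based with inclusive windows; windows touching at their
boundary are merged.  LD is computed directly from a reference panel's
dosage matrix.  Power utilities evaluate the noncentral chi-square at a
genome-wide alpha, with the noncentrality ncp = N * (variance fraction
explained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Signal",
    "Locus",
    "LdPanel",
    "ld_r2",
    "clump",
    "define_loci",
    "overlap_sets",
    "power_noncentral",
    "ncp_from_r2",
    "expected_hits",
    "write_loci_bed",
    "read_loci_bed",
]


@dataclass
class Signal:
    lead: str
    chrom: int
    pos: int
    p: float
    members: List[str] = field(default_factory=list)


@dataclass
class Locus:
    chrom: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    signals: List[Signal] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class LdPanel:
    """Reference dosage panel with SNP-id column lookup."""

    def __init__(self, dosages: np.ndarray, snp_ids: Sequence[str]):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape[1] != len(snp_ids):
            raise ValueError("snp_ids must match the panel's column count")
        self.dosages = dosages
        self.index = {s: j for j, s in enumerate(snp_ids)}

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.index[snp_id]]


def ld_r2(panel: LdPanel, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of two SNPs' dosages in the panel."""
    gi = panel.column(snp_i)
    gj = panel.column(snp_j)
    if np.ptp(gi) == 0 or np.ptp(gj) == 0:
        raise ValueError("monomorphic SNP in LD panel")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def clump(
    sumstats: pd.DataFrame,
    panel: LdPanel,
    p_col: str = "P_2DF",
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.2,
    window_kb: float = 500.0,
) -> List[Signal]:
    """Greedy LD clumping of significant SNPs into independent signals.

    Every SNP below p_threshold ends up in exactly one signal, as lead or
    member.  Ties on p are broken by ascending (chr, pos), which makes the
    result invariant to input row order.
    """
    sig = sumstats.loc[sumstats[p_col] < p_threshold,
                      ["SNPID", "CHR", "POS", p_col]].copy()
    sig = sig.sort_values([p_col, "CHR", "POS"], kind="mergesort",
                          ignore_index=True)
    window = int(window_kb * 1000)
    assigned = np.zeros(len(sig), dtype=bool)
    signals: List[Signal] = []
    for i in range(len(sig)):
        if assigned[i]:
            continue
        lead = sig.iloc[i]
        assigned[i] = True
        members = []
        lead_g = panel.column(lead["SNPID"])
        for j in range(len(sig)):
            if assigned[j]:
                continue
            cand = sig.iloc[j]
            if cand["CHR"] != lead["CHR"]:
                continue
            if abs(int(cand["POS"]) - int(lead["POS"])) > window:
                continue
            g = panel.column(cand["SNPID"])
            if np.ptp(g) == 0:
                continue
            r = np.corrcoef(lead_g, g)[0, 1]
            if r * r >= r2_threshold:
                assigned[j] = True
                members.append(cand["SNPID"])
        signals.append(
            Signal(
                lead=lead["SNPID"],
                chrom=int(lead["CHR"]),
                pos=int(lead["POS"]),
                p=float(lead[p_col]),
                members=members,
            )
        )
    return signals


def define_loci(signals: Sequence[Signal], flank_kb: float = 500.0) -> List[Locus]:
    """Merge +/-flank windows around signals into associated loci.

    Windows are clipped at position 1; windows that overlap or touch on the
    same chromosome are merged, so loci are pairwise disjoint and each
    spans at least 2*flank (>= 1 Mb at the default).
    """
    flank = int(flank_kb * 1000)
    intervals = sorted(
        (s.chrom, max(1, s.pos - flank), s.pos + flank, s) for s in signals
    )
    loci: List[Locus] = []
    for chrom, start, end, s in intervals:
        if loci and loci[-1].chrom == chrom and start <= loci[-1].end:
            loci[-1].end = max(loci[-1].end, end)
            loci[-1].signals.append(s)
        else:
            loci.append(Locus(chrom=chrom, start=start, end=end, signals=[s]))
    return loci


def _loci_overlap(a: Locus, b: Locus) -> bool:
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def overlap_sets(named_sets: Dict[str, object]) -> Dict[frozenset, int]:
    """Venn-cell counts for >= 2 named sets of hashable keys or loci.

    For plain sets the cells partition the union of elements.  For lists of
    loci, the union of all intervals is first merged into disjoint
    reference regions; each region's membership pattern records which
    input sets intersect it, and cells count reference regions.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    names = list(named_sets)
    first = next(iter(named_sets.values()))
    if len(first) > 0 and isinstance(next(iter(first)), Locus):
        all_loci = [(name, loc) for name in names for loc in named_sets[name]]
        merged: List[Locus] = []
        for _, loc in sorted(all_loci, key=lambda t: (t[1].chrom, t[1].start)):
            if merged and merged[-1].chrom == loc.chrom and loc.start <= merged[-1].end:
                merged[-1].end = max(merged[-1].end, loc.end)
            else:
                merged.append(Locus(loc.chrom, loc.start, loc.end))
        cells: Dict[frozenset, int] = {}
        for region in merged:
            pattern = frozenset(
                name
                for name in names
                if any(_loci_overlap(region, loc) for loc in named_sets[name])
            )
            cells[pattern] = cells.get(pattern, 0) + 1
        return cells
    sets = {name: set(v) for name, v in named_sets.items()}
    universe = set().union(*sets.values())
    cells = {}
    for el in universe:
        pattern = frozenset(name for name in names if el in sets[name])
        cells[pattern] = cells.get(pattern, 0) + 1
    return cells


def power_noncentral(ncp: float, df: int, alpha: float) -> float:
    """Power of the chi-square(df) test at level alpha and noncentrality ncp.

    df=1 uses the exact normal form Phi(sqrt(ncp) - z_c) +
    Phi(-sqrt(ncp) - z_c); df=2 uses the noncentral chi-square survival
    function at the central critical value.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if ncp < 0:
        raise ValueError("noncentrality must be >= 0")
    if df == 1:
        zc = stats.norm.isf(alpha / 2.0)
        s = np.sqrt(ncp)
        return float(stats.norm.cdf(s - zc) + stats.norm.cdf(-s - zc))
    crit = stats.chi2.isf(alpha, df=df)
    if ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df=df, nc=ncp))


def ncp_from_r2(r2_fraction: float, N: float) -> float:
    """Noncentrality implied by a variance fraction explained: N * r2."""
    return float(N) * float(r2_fraction)


def expected_hits(effects: Sequence[tuple], alpha: float, df: int = 1) -> float:
    """Expected number of detections across SNPs: sum of per-SNP powers.

    effects: iterable of (beta, f, N_target, var_Y); each SNP contributes
    power(ncp, df, alpha) with ncp = N_target * 2 f (1-f) beta^2 / var_Y.
    """
    total = 0.0
    for beta, f, n_target, var_y in effects:
        ncp = n_target * 2.0 * f * (1.0 - f) * beta**2 / var_y
        total += power_noncentral(ncp, df=df, alpha=alpha)
    return total


def write_loci_bed(loci: Sequence[Locus], path) -> None:
    """Write loci as BED-like TSV (0-based half-open on disk)."""
    rows = [
        {
            "chrom": loc.chrom,
            "start": loc.start - 1,  # 1-based inclusive -> 0-based half-open
            "end": loc.end,
            "n_signals": len(loc.signals),
            "lead_snps": ",".join(s.lead for s in loc.signals),
        }
        for loc in loci
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "n_signals", "lead_snps"]).to_csv(
        path, sep="\t", index=False
    )


def read_loci_bed(path) -> List[Locus]:
    """Read the BED-like loci TSV back to 1-based inclusive loci."""
    df = pd.read_csv(path, sep="\t")
    return [
        Locus(chrom=int(r["chrom"]), start=int(r["start"]) + 1, end=int(r["end"]))
        for _, r in df.iterrows()
    ]
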