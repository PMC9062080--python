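"""Downstream genomic analytics on compartment calls.

Covers region segmentation and length/coverage statistics, cross-cell-line
conservation of the A/B identity of regions, neighbourhood (junction-type)
enrichment against a length-preserving permutation null, border
classification between the four-state and A/B schemes, flanking-signal
matrices at borders, signal and chromatin-state (ChromHMM-style) enrichment,
and concordance between compartmental-state switches and differential gene
expression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ABCall, ACTIVITY_ORDER, CompartmentCall
from .matrix_io import SignalTrack

log = logging.getLogger(__name__)

MICRO_STATES = ("A2", "B2")


@dataclass
class RegionSet:
    """Maximal runs of same-state bins as (chrom, start, end, state) rows."""

    regions: pd.DataFrame  # columns chrom, start, end, state

    def __len__(self):
        return len(self.regions)

    @property
    def lengths(self) -> np.ndarray:
        return (self.regions["end"] - self.regions["start"]).to_numpy()

    def junctions(self) -> pd.DataFrame:
        """Contiguous boundaries between adjacent regions: position + flanks."""
        rows = []
        df = self.regions
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            prev = None
            for row in grp.itertuples():
                if prev is not None and prev.end == row.start:
                    rows.append((chrom, row.start, prev.state, row.state))
                prev = row
        return pd.DataFrame(rows, columns=["chrom", "position", "left", "right"])


@dataclass
class BorderSet:
    """Borders with flank states and scheme-specificity annotation."""

    borders: pd.DataFrame
    # columns: chrom, position, left, right, scheme_class, micro_associated

    def __len__(self):
        return len(self.borders)

    def counts(self) -> dict:
        return self.borders["scheme_class"].value_counts().to_dict()


@dataclass
class EnrichmentTable:
    rows: pd.DataFrame
    n_perm: int = 0
    seed: int = None
    distributions: dict = field(default_factory=dict)


def segment(call: CompartmentCall) -> RegionSet:
    """Run-length encode per-bin states; NA bins terminate runs."""
    b = call.binning
    rows = []
    start = None
    cur = None
    for i in range(b.n_bins):
        s = call.states[i]
        if s == "NA":
            if cur is not None:
                rows.append((b.chrom, start, i * b.bin_size, cur))
                cur = None
            continue
        if s != cur:
            if cur is not None:
                rows.append((b.chrom, start, i * b.bin_size, cur))
            cur, start = s, i * b.bin_size
    if cur is not None:
        rows.append((b.chrom, start, b.n_bins * b.bin_size, cur))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


def segment_ab(call: ABCall) -> RegionSet:
    proxy = CompartmentCall(
        binning=call.binning,
        states=call.compartments,
        ev1=call.ev1,
        ev2=np.full_like(call.ev1, np.nan),
    )
    return segment(proxy)


def expand(rs: RegionSet, binning) -> np.ndarray:
    """Regions back to per-bin states; uncovered bins are NA."""
    states = np.array(["NA"] * binning.n_bins, dtype=object)
    for row in rs.regions.itertuples():
        states[row.start // binning.bin_size : row.end // binning.bin_size] = row.state
    return states


def coverage_and_lengths(rs: RegionSet):
    """Per-state fraction of covered (non-NA) bp and per-state length lists."""
    if len(rs) == 0:
        raise ValueError("empty region set")
    df = rs.regions.assign(length=rs.lengths)
    total = df["length"].sum()
    fractions = (df.groupby("state")["length"].sum() / total).to_dict()
    lengths = {s: g["length"].to_numpy() for s, g in df.groupby("state")}
    return fractions, lengths


def conservation_score(ab_calls, rs: RegionSet) -> pd.DataFrame:
    """Per-region conservation of A/B identity across cell lines.

    Each cell line votes A or B by the majority label over the region's bins;
    score = (nA - nB)/N with N the number of voting lines. 1 means A in every
    line, -1 means B in every line. Lines whose call is entirely NA over the
    region (or exactly tied) do not vote.
    """
    if not ab_calls:
        raise ValueError("need at least one cell-line A/B call")
    scores = []
    for row in rs.regions.itertuples():
        n_a = n_b = 0
        for call in ab_calls:
            b0 = row.start // call.binning.bin_size
            b1 = row.end // call.binning.bin_size
            seg = call.compartments[b0:b1]
            a_bins = int((seg == "A").sum())
            b_bins = int((seg == "B").sum())
            if a_bins > b_bins:
                n_a += 1
            elif b_bins > a_bins:
                n_b += 1
        n = n_a + n_b
        scores.append((n_a - n_b) / n if n else np.nan)
    out = rs.regions.copy()
    out["conservation"] = scores
    return out


def _junction_proportions(labels, contiguous) -> dict:
    """Unordered adjacent-pair proportions among differing, contiguous junctions."""
    counts = {}
    total = 0
    for i in range(len(labels) - 1):
        if not contiguous[i]:
            continue
        a, b = labels[i], labels[i + 1]
        if a == b:
            continue
        key = tuple(sorted((a, b)))
        counts[key] = counts.get(key, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def neighborhood_enrichment(
    rs: RegionSet, n_perm: int = 1000, seed: int = 0
) -> EnrichmentTable:
    """Enrichment of adjacent state-pair types against a permutation null.

    The null shuffles the order of region labels while keeping region lengths
    and positions fixed; junctions between same-label neighbours after
    shuffling are dropped. Enrichment = observed proportion / mean permuted
    proportion of each unordered pair type.
    """
    if len(rs) < 2:
        raise ValueError("need at least two regions")
    rng = np.random.default_rng(seed)
    df = rs.regions
    labels = df["state"].to_numpy()
    order = df.sort_values(["chrom", "start"]).index.to_numpy()
    labels = labels[order]
    sorted_df = df.loc[order]
    contiguous = (
        (sorted_df["end"].to_numpy()[:-1] == sorted_df["start"].to_numpy()[1:])
        & (sorted_df["chrom"].to_numpy()[:-1] == sorted_df["chrom"].to_numpy()[1:])
    )
    observed = _junction_proportions(labels, contiguous)
    states = sorted(set(labels))
    pair_types = [tuple(sorted(p)) for p in itertools.combinations(states, 2)]
    dists = {p: np.zeros(n_perm) for p in pair_types}
    for t in range(n_perm):
        perm = _junction_proportions(rng.permutation(labels), contiguous)
        for p in pair_types:
            dists[p][t] = perm.get(p, 0.0)
    rows = []
    for p in pair_types:
        obs = observed.get(p, 0.0)
        exp = dists[p].mean()
        if exp > 0:
            enr = obs / exp
        else:
            enr = np.inf if obs > 0 else np.nan
        rows.append(("-".join(p), obs, exp, enr))
    table = pd.DataFrame(rows, columns=["pair", "observed", "expected", "enrichment"])
    return EnrichmentTable(table, n_perm=n_perm, seed=seed, distributions=dists)


def classify_borders(mosaic_rs: RegionSet, ab_rs: RegionSet) -> BorderSet:
    """Classify borders as scheme-specific or overlapping (exact edge match).

    A border is 'overlapping' when the two schemes place a junction at the
    identical bp position on the same chromosome. A four-state border is
    micro-associated when either flank is A2 or B2.
    """
    mj = mosaic_rs.junctions()
    aj = ab_rs.junctions()
    ab_pos = set(zip(aj["chrom"], aj["position"]))
    mo_pos = set(zip(mj["chrom"], mj["position"]))
    rows = []
    for row in mj.itertuples():
        cls = "overlapping" if (row.chrom, row.position) in ab_pos else "mosaic_specific"
        micro = row.left in MICRO_STATES or row.right in MICRO_STATES
        rows.append((row.chrom, row.position, row.left, row.right, cls, micro))
    for row in aj.itertuples():
        if (row.chrom, row.position) not in mo_pos:
            rows.append((row.chrom, row.position, row.left, row.right, "ab_specific", False))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "position", "left", "right", "scheme_class", "micro_associated"],
    ).sort_values(["chrom", "position"], ignore_index=True)
    return BorderSet(df)


def border_signal_matrix(
    bs: BorderSet, track: SignalTrack, flank_bins: int = 10
) -> tuple:
    """N x (2*flank_bins) matrix of per-bin signal around each border.

    Each row lists the track values in ``flank_bins`` bins left then right of
    the border, in genomic order (left flank = listed left state). Borders
    within a flank of the chromosome end, or with a fully missing flank, are
    dropped with a logged count.
    """
    b = track.binning
    rows, kept = [], []
    dropped = 0
    for row in bs.borders.itertuples():
        if row.chrom != b.chrom or row.position % b.bin_size != 0:
            dropped += 1
            continue
        e = row.position // b.bin_size
        if e - flank_bins < 0 or e + flank_bins > b.n_bins:
            dropped += 1
            continue
        window = track.values[e - flank_bins : e + flank_bins]
        left, right = window[:flank_bins], window[flank_bins:]
        if np.all(~np.isfinite(left)) or np.all(~np.isfinite(right)):
            dropped += 1
            continue
        rows.append(window)
        kept.append(row.Index)
    if dropped:
        log.info("border_signal_matrix: dropped %d borders", dropped)
    matrix = np.array(rows) if rows else np.empty((0, 2 * flank_bins))
    return matrix, bs.borders.loc[kept].reset_index(drop=True)


def signal_enrichment(call: CompartmentCall, track: SignalTrack) -> EnrichmentTable:
    """Per-state signal enrichment: state median / overall median."""
    valid = call.binning.valid & np.isfinite(track.values)
    total_med = np.median(track.values[valid])
    rows = []
    for s in sorted(set(call.states[valid])):
        mask = valid & (call.states == s)
        med = np.median(track.values[mask])
        enr = med / total_med if total_med != 0 else np.nan
        rows.append((track.name or "signal", s, enr, int(mask.sum())))
    if total_med == 0:
        log.warning("signal_enrichment: total median is 0; enrichments undefined")
    return EnrichmentTable(
        pd.DataFrame(rows, columns=["category", "state", "enrichment", "n"])
    )


def chromhmm_enrichment(call: CompartmentCall, annotation: pd.DataFrame) -> EnrichmentTable:
    """Chromatin-state annotation enrichment per compartmental state.

    Annotations are binned into the call's bins as covered-bp proportions;
    enrichment = mean proportion within the state / mean over all valid bins.
    Labels absent from the chromosome are omitted.
    """
    b = call.binning
    rows = []
    ann = annotation[annotation["chrom"] == b.chrom]
    valid = b.valid
    for label, grp in ann.groupby("label"):
        prop = np.zeros(b.n_bins)
        for iv in grp.itertuples():
            start, end = max(iv.start, 0), min(iv.end, b.n_bins * b.bin_size)
            if end <= start:
                continue
            b0, b1 = start // b.bin_size, (end - 1) // b.bin_size
            for i in range(b0, b1 + 1):
                lo = max(start, i * b.bin_size)
                hi = min(end, (i + 1) * b.bin_size)
                prop[i] += (hi - lo) / b.bin_size
        overall = prop[valid].mean()
        if overall == 0:
            continue
        for s in sorted(set(call.states[valid])):
            mask = valid & (call.states == s)
            rows.append((label, s, prop[mask].mean() / overall, int(mask.sum())))
    return EnrichmentTable(
        pd.DataFrame(rows, columns=["category", "state", "enrichment", "n"])
    )


def filter_degs(
    degs: pd.DataFrame, min_change: float = 0.5, max_p: float = 0.05, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Differential-expression filter: >50% change relative to the smaller
    FPKM and p < threshold. A pseudocount guards zero FPKM ratios."""
    e1 = degs["expr1"].to_numpy(dtype=float) + pseudocount
    e2 = degs["expr2"].to_numpy(dtype=float) + pseudocount
    change = np.abs(e2 - e1) / np.minimum(e1, e2)
    keep = (change > min_change) & (degs["pvalue"].to_numpy(dtype=float) < max_p)
    return degs[keep].reset_index(drop=True)


def switch_concordance(
    call1: CompartmentCall,
    call2: CompartmentCall,
    degs: pd.DataFrame,
    prefilter: bool = False,
    pseudocount: float = 0.01,
) -> dict:
    """Concordance between compartmental-state switches and expression change.

    States are ranked by transcriptional activity B1 < B2 < A2 < A1 (and
    B < A for the collapsed scheme). A gene's region 'switches' when its
    state rank changes between the two conditions; the switch is concordant
    when the rank-change direction matches the sign of the expression change
    (condition 2 over condition 1). Returns per-gene table plus counts for
    both the four-state and A/B schemes.
    """
    if prefilter:
        degs = filter_degs(degs, pseudocount=pseudocount)
    b = call1.binning

    def ab_from_ev1(call):
        # the A/B baseline follows the sign of EV1, not the four-state names:
        # a micro state embedded in compartment A typically keeps positive EV1
        out = np.array(["NA"] * call.binning.n_bins, dtype=object)
        finite = np.isfinite(call.ev1) & call.binning.valid
        out[finite & (call.ev1 >= 0)] = "A"
        out[finite & (call.ev1 < 0)] = "B"
        return out

    ab1, ab2 = ab_from_ev1(call1), ab_from_ev1(call2)
    ab_rank = {"B": 0, "A": 1, "NA": 0}
    rows = []
    excluded = 0
    for g in degs.itertuples():
        if g.chrom != b.chrom:
            excluded += 1
            continue
        i = b.bin_of(int(g.position))
        if i < 0:
            excluded += 1
            continue
        s1, s2 = call1.states[i], call2.states[i]
        if s1 not in ACTIVITY_ORDER or s2 not in ACTIVITY_ORDER:
            excluded += 1
            continue
        expr_sign = int(np.sign(np.log((g.expr2 + pseudocount) / (g.expr1 + pseudocount))))
        dr = ACTIVITY_ORDER[s2] - ACTIVITY_ORDER[s1]
        switched = dr != 0
        direction = int(np.sign(dr))
        concordant = switched and expr_sign != 0 and direction == expr_sign
        a1, a2 = ab1[i], ab2[i]
        ab_dr = ab_rank[a2] - ab_rank[a1]
        ab_switched = ab_dr != 0
        ab_concordant = ab_switched and expr_sign != 0 and int(np.sign(ab_dr)) == expr_sign
        rows.append(
            (g.gene, g.chrom, g.position, s1, s2, switched, direction, expr_sign,
             concordant, a1, a2, ab_switched, ab_concordant)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "position", "state1", "state2", "switched",
            "direction", "expr_sign", "concordant", "ab1", "ab2",
            "ab_switched", "ab_concordant",
        ],
    )
    return {
        "table": table,
        "n_genes": len(table),
        "n_excluded": excluded,
        "mosaic_switched": int(table["switched"].sum()),
        "mosaic_concordant": int(table["concordant"].sum()),
        "ab_switched": int(table["ab_switched"].sum()),
        "ab_concordant": int(table["ab_concordant"].sum()),
    }
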