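"""Planted four-state plaid matrices and matched tracks for desk-scale testing.

The generator emulates the characteristic layout of compartmental states on a
chromosome: long alternating A1/B1 blocks (canonical euchromatin and
constitutive heterochromatin) with short "micro-compartment" runs embedded in
the major state of opposite activity — B2 (facultative, H3K27me3-marked
heterochromatin) inside A1, and A2 (weakly active euchromatin) inside B1. The
contact map is an O/E-like block matrix: every bin pair draws its level from
a state-pair affinity table with multiplicative log-normal noise, with the
strongest segregation between A1 and B1, a weaker A2/B2 contrast and, like a
real O/E matrix, no residual distance decay unless requested.

Defaults put the major states near 70% of the chromosome and the micro
states near 30%, with micro runs much shorter than major blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .eigen import ArmAnnotation
from .matrix_io import ContactMatrix, GenomicBinning, SignalTrack

#: state-pair mean O/E levels; within > cross, A1-B1 minimal, micro contrasts weaker
DEFAULT_AFFINITY = {
    ("A1", "A1"): 1.6,
    ("B1", "B1"): 1.6,
    ("A2", "A2"): 1.4,
    ("B2", "B2"): 1.4,
    ("A1", "B1"): 0.4,
    ("A2", "B2"): 0.7,
    ("A1", "B2"): 0.8,
    ("A2", "B1"): 0.8,
    ("A1", "A2"): 1.1,
    ("B1", "B2"): 1.1,
}

#: track means per state: (active mark, H3K27me3-like, expression)
DEFAULT_TRACK_MEANS = {
    "A1": (10.0, 1.0, 10.0),
    "A2": (6.0, 1.0, 5.0),
    "B2": (2.0, 8.0, 1.5),
    "B1": (2.0, 1.0, 0.5),
}


@dataclass
class SyntheticParams:
    """Generator knobs; the defaults define the study conditions.

    major_mean_len / micro_mean_len are geometric mean run lengths in bins;
    micro_rate is the per-bin probability of starting a micro run inside a
    major block (0 disables micro states). With the defaults the expected
    micro fraction is ~0.3 of the chromosome.
    """

    bin_size: int = 100_000
    major_mean_len: float = 30.0
    micro_mean_len: float = 3.0
    micro_rate: float = 1.0 / 6.0
    affinity: dict = field(default_factory=lambda: dict(DEFAULT_AFFINITY))
    noise_sigma: float = 0.2
    decay_alpha: float = None  # optional power-law decay exponent; None = off
    track_means: dict = field(default_factory=lambda: dict(DEFAULT_TRACK_MEANS))
    track_noise_sd: float = 1.0
    cen_fraction: float = 0.02  # centromere gap (invalid bins) as chromosome fraction

    def validate(self):
        if self.micro_rate > 0 and self.micro_mean_len >= self.major_mean_len:
            raise ParameterError("micro mean run length must be < major block length")
        for pair, level in _full_affinity(self.affinity).items():
            if level <= 0:
                raise ParameterError(f"non-positive affinity for {pair}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["affinity"] = {f"{a}-{b}": v for (a, b), v in self.affinity.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticParams":
        d = json.loads(text)
        d["affinity"] = {tuple(k.split("-")): v for k, v in d["affinity"].items()}
        d["track_means"] = {k: tuple(v) for k, v in d["track_means"].items()}
        return cls(**d)


def _full_affinity(table: dict) -> dict:
    out = {}
    for (a, b), v in table.items():
        out[(a, b)] = v
        out[(b, a)] = v
    return out


@dataclass
class SyntheticTruth:
    """Planted per-bin states plus the parameters that generated them."""

    binning: GenomicBinning
    states: np.ndarray  # 'A1'/'A2'/'B1'/'B2'/'NA'
    params: SyntheticParams
    seed: int

    @property
    def arms(self) -> ArmAnnotation:
        n = self.binning.n_bins
        gap = max(int(round(self.params.cen_fraction * n)), 0)
        mid = n // 2
        return ArmAnnotation(
            chrom=self.binning.chrom,
            p=(0, mid - gap // 2),
            cen=(mid - gap // 2, mid - gap // 2 + gap),
            q=(mid - gap // 2 + gap, n),
        )

    def labels_valid(self) -> np.ndarray:
        return self.states[self.binning.valid]


def _geometric_len(rng, mean: float) -> int:
    return int(rng.geometric(min(1.0 / max(mean, 1.0), 1.0)))


def generate_truth(
    n_bins: int, params: SyntheticParams = None, seed: int = 0, chrom: str = "chrS"
) -> SyntheticTruth:
    """Plant a four-state layout: alternating major A1/B1 blocks with short
    micro runs (B2 inside A1, A2 inside B1) separated from block edges so
    every micro run is embedded in its host state."""
    if n_bins < 50:
        raise ParameterError("need at least 50 bins")
    params = params or SyntheticParams()
    params.validate()
    rng = np.random.default_rng(seed)
    states = np.empty(n_bins, dtype=object)
    pos = 0
    major = "A1"
    while pos < n_bins:
        block_len = max(_geometric_len(rng, params.major_mean_len), 3)
        block_len = min(block_len, n_bins - pos)
        block = np.array([major] * block_len, dtype=object)
        micro = "B2" if major == "A1" else "A2"
        if params.micro_rate > 0 and block_len > 4:
            i = 1  # keep the first bin major so micros stay embedded
            while i < block_len - 1:
                if rng.random() < params.micro_rate:
                    run = min(_geometric_len(rng, params.micro_mean_len), block_len - 1 - i)
                    if run > 0:
                        block[i : i + run] = micro
                        i += run + 1  # at least one major bin after the run
                        continue
                i += 1
        states[pos : pos + block_len] = block
        pos += block_len
        major = "B1" if major == "A1" else "A1"
    binning = GenomicBinning(chrom, params.bin_size, n_bins)
    # centromere gap: invalid bins in the middle
    gap = max(int(round(params.cen_fraction * n_bins)), 0)
    if gap:
        mid = n_bins // 2
        lo = mid - gap // 2
        binning.valid[lo : lo + gap] = False
        states[lo : lo + gap] = "NA"
    return SyntheticTruth(binning, states, params, seed)


def generate_matrix(truth: SyntheticTruth, seed: int = None) -> ContactMatrix:
    """O/E-like block matrix from the planted states.

    Entry (i, j) = affinity(state_i, state_j) x optional power-law decay x
    log-normal noise; symmetric and non-negative. Rows of invalid bins are 0.
    """
    params = truth.params
    params.validate()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    n = truth.binning.n_bins
    aff = _full_affinity(params.affinity)
    states = truth.states
    base = np.zeros((n, n))
    valid = truth.binning.valid
    vi = np.flatnonzero(valid)
    codes = {s: i for i, s in enumerate(("A1", "A2", "B1", "B2"))}
    lab = np.array([codes.get(s, -1) for s in states])
    table = np.zeros((4, 4))
    for (a, b), v in aff.items():
        table[codes[a], codes[b]] = v
    base[np.ix_(vi, vi)] = table[np.ix_(lab[vi], lab[vi])]
    if params.decay_alpha is not None:
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) + 1.0
        base *= d ** (-params.decay_alpha)
    if params.noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=params.noise_sigma, size=(n, n))
        noise = np.sqrt(noise * noise.T)  # symmetric multiplicative noise
        base *= noise
    base = (base + base.T) / 2.0
    return ContactMatrix(truth.binning.copy(), base, kind="oe")


def generate_tracks(truth: SyntheticTruth, seed: int = None):
    """Matched active-mark, H3K27me3-like and expression tracks.

    Active mark: A1 > A2 > B2 ~ B1. H3K27me3: high only on B2. Expression:
    A1 > A2 > B2 >= B1. Gaussian noise, clipped at 0; NaN on invalid bins.
    """
    params = truth.params
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    n = truth.binning.n_bins
    tracks = []
    for j, name in enumerate(("active", "h3k27me3", "expression")):
        vals = np.full(n, np.nan)
        for s, means in params.track_means.items():
            mask = truth.states == s
            vals[mask] = np.clip(
                means[j] + rng.normal(0.0, params.track_noise_sd, mask.sum()), 0.0, None
            )
        vals[~truth.binning.valid] = np.nan
        tracks.append(SignalTrack(truth.binning.copy(), vals, name=name))
    return tuple(tracks)


def write_truth_bed(path, truth: SyntheticTruth, header_lines=()) -> None:
    b = truth.binning
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        start, cur = 0, None
        for i in range(b.n_bins + 1):
            s = truth.states[i] if i < b.n_bins else None
            if s != cur:
                if cur is not None and cur != "NA":
                    fh.write(f"{b.chrom}\t{start * b.bin_size}\t{i * b.bin_size}\t{cur}\n")
                start, cur = i, s


def write_arms_tsv(path, truth: SyntheticTruth, header_lines=()) -> None:
    arms = truth.arms
    bs = truth.binning.bin_size
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            f"{truth.binning.chrom}\t{arms.p[1] * bs}\t{arms.cen[1] * bs}"
            f"\t{truth.binning.n_bins * bs}\n"
        )
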