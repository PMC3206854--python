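"""Sequence-logo construction with Metropolis-annealed offset correction.

Each trained network carries its own picture of the motif, which is made
explicit by scoring a large set of random background peptides and stacking
the cores of the top-scoring 1% into a position-specific frequency matrix
(PSSM).  Networks trained from different starting points may settle on
shifted registers of the same motif; overlaying them directly would smear
the logo.  The offset correction aligns the per-network PSSMs by a
simulated-annealing search (Metropolis acceptance min(1, exp(dI/T)) with a
geometrically cooled temperature) over integer column shifts, maximising
the information content of the combined matrix.  The re-aligned cores are
pooled into the final logo; a log-odds matrix against the background
composition (in half-bit units) is derived from the pooled frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA_ORDER, BACKGROUND_FREQS, COLOR_CLASSES, peptides_to_codes
from .encoding import encode_peptides
from .network import TrainedNetwork, score_batch

LOG2_20 = math.log2(20)
#: flat pseudocount added per residue per column before normalising
PSEUDOCOUNT = 1.0 / 20.0
#: background-scoring chunk size (bounds the encoded-matrix memory)
CHUNK = 10_000


@dataclass
class PSSM:
    """Per-position amino-acid relative frequencies over aligned cores."""

    freqs: np.ndarray      # (motif_len, 20), rows sum to 1
    n_cores: int
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 20:
            raise ValueError("PSSM frequencies must have shape (motif_len, 20)")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSSM rows must sum to 1")
        if (self.freqs < 0).any():
            raise ValueError("PSSM frequencies must be non-negative")

    @property
    def motif_len(self) -> int:
        return self.freqs.shape[0]


@dataclass
class LogoData:
    """Numeric content of a sequence logo.

    ``R`` is the per-position information content in bits, ``heights`` the
    letter heights h = f * R; columns follow ``alphabet`` order and letters
    carry chemical-property colour classes.
    """

    R: np.ndarray            # (motif_len,)
    heights: np.ndarray      # (motif_len, 20)
    alphabet: str = AA_ORDER
    colors: dict = field(default_factory=lambda: dict(COLOR_CLASSES))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.heights, columns=list(self.alphabet))
        df.insert(0, "info_bits", self.R)
        df.insert(0, "pos", np.arange(1, len(self.R) + 1))
        return df


@dataclass
class OffsetState:
    offsets: np.ndarray
    combined_info: float
    temperature: float


def generate_background_peptides(count: int, length: int, seed: int) -> list[str]:
    """Random peptides drawn i.i.d. per position from the bundled
    background amino-acid composition; deterministic given seed."""
    if count < 1 or length < 1:
        raise ValueError("count and length must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(20, size=(count, length), p=BACKGROUND_FREQS)
    letters = np.frombuffer(AA_ORDER.encode("ascii"), dtype=np.uint8)
    ascii_arr = letters[codes]
    flat = ascii_arr.reshape(count, length).view(f"S{length}").ravel()
    return [s.decode("ascii") for s in flat]


def column_frequencies(cores: Sequence[str], pseudocount: float = 0.0) -> np.ndarray:
    """Stack equal-length cores into per-position residue frequencies.

    'X' residues are spread uniformly over the 20 columns.
    """
    if not cores:
        raise ValueError("empty core stack")
    m = len(cores[0])
    if any(len(c) != m for c in cores):
        raise ValueError("cores must share one length")
    counts = np.full((m, 20), pseudocount, dtype=np.float64)
    for codes in peptides_to_codes(list(cores)):
        for i, c in enumerate(codes):
            if c == 20:
                counts[i] += 1.0 / 20.0
            else:
                counts[i, c] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def _score_background(
    networks: Sequence[TrainedNetwork], peptides: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Best-core offsets and scores of every network on every peptide.

    The peptides are encoded once per chunk and shared across networks
    (all members of an ensemble use one encoding configuration).
    Returns arrays of shape (n_networks, n_peptides).
    """
    n = len(peptides)
    offsets = np.empty((len(networks), n), dtype=np.int64)
    scores = np.empty((len(networks), n))
    for lo in range(0, n, CHUNK):
        chunk = list(peptides[lo : lo + CHUNK])
        enc = encode_peptides(chunk, networks[0].config)
        for k, net in enumerate(networks):
            offs, sc = score_batch(net, enc)
            offsets[k, lo : lo + len(chunk)] = offs
            scores[k, lo : lo + len(chunk)] = sc
    return offsets, scores


def _top_cores(
    peptides: Sequence[str], offsets: np.ndarray, scores: np.ndarray,
    top_fraction: float, motif_len: int,
) -> list[tuple[int, int]]:
    """(peptide index, core offset) of the top-scoring fraction; ties at
    the cutoff broken by input order (stable sort)."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    k = math.ceil(top_fraction * len(peptides))
    if k < 1:
        raise ValueError("top fraction selects no peptides")
    top = np.argsort(-scores, kind="stable")[:k]
    return [(int(i), int(offsets[i])) for i in top]


def network_pssm(
    network: TrainedNetwork,
    background_peptides: Sequence[str],
    top_fraction: float = 0.01,
) -> tuple[PSSM, list[tuple[int, int]]]:
    """PSSM of a single network from its top-scoring background peptides.

    Every background peptide is scored via its best core; the cores of the
    ceil(top_fraction * count) highest-scoring peptides (ties at the
    cutoff broken by input order) are stacked into a pseudocounted PSSM.
    Returns the PSSM and the (peptide index, core offset) pairs used.
    """
    offsets, scores = _score_background([network], background_peptides)
    m = network.config.motif_len
    picked = _top_cores(background_peptides, offsets[0], scores[0], top_fraction, m)
    cores = [background_peptides[i][o : o + m] for i, o in picked]
    freqs = column_frequencies(cores, pseudocount=PSEUDOCOUNT)
    return PSSM(freqs=freqs, n_cores=len(cores), pseudocount=PSEUDOCOUNT), picked


def _info_bits(freqs: np.ndarray) -> np.ndarray:
    """R_i = log2(20) + sum_a f log2 f per row, with 0*log2(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    return LOG2_20 + plogp.sum(axis=1)


def combined_information(pssms: Sequence[PSSM], offsets: Sequence[int]) -> float:
    """Information content (bits) of the offset-shifted, averaged matrix.

    PSSM k's column c sits at consensus position c + offsets[k]; columns
    covered by every PSSM are averaged and their R_i summed.  An empty
    common window scores -inf (such a move is always rejected).
    """
    if len(pssms) != len(offsets):
        raise ValueError("one offset per PSSM required")
    m = pssms[0].motif_len
    if any(p.motif_len != m for p in pssms):
        raise ValueError("PSSMs must share one motif length")
    lo = max(offsets)
    hi = min(offsets) + m - 1
    if lo > hi:
        return -np.inf
    width = hi - lo + 1
    acc = np.zeros((width, 20))
    for p, o in zip(pssms, offsets):
        acc += p.freqs[lo - o : lo - o + width]
    acc /= len(pssms)
    return float(_info_bits(acc).sum())


@dataclass
class AnnealSchedule:
    t_start: float = 1.0
    t_end: float = 0.01
    cooling: float = 0.95
    proposals_per_step: int = 20   # multiplied by the number of PSSMs
    final_proposals: int = 200     # likewise


def offset_correction(
    pssms: Sequence[PSSM],
    max_shift: int = 4,
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
) -> np.ndarray:
    """Anneal integer column offsets that maximise combined information.

    Starts from all-zero offsets; proposes +/-1 shifts of one randomly
    chosen PSSM within +/-max_shift; accepts with probability
    min(1, exp(dI / T)); T is cooled geometrically.  Returns the best
    state seen, re-centred so the (lower) median offset is zero — the
    result is therefore never worse than the unshifted overlay.
    Deterministic given seed.
    """
    schedule = schedule or AnnealSchedule()
    n = len(pssms)
    if n == 0:
        raise ValueError("need at least one PSSM")
    offsets = np.zeros(n, dtype=np.int64)
    if n == 1:
        return offsets
    rng = np.random.default_rng(seed)
    current = combined_information(pssms, offsets)
    best = current
    best_offsets = offsets.copy()
    temps = []
    t = schedule.t_start
    while t > schedule.t_end:
        temps.append((t, schedule.proposals_per_step * n))
        t *= schedule.cooling
    temps.append((schedule.t_end, schedule.final_proposals * n))
    for t, n_prop in temps:
        for _ in range(n_prop):
            k = int(rng.integers(n))
            step = 1 if rng.random() < 0.5 else -1
            if abs(offsets[k] + step) > max_shift:
                continue
            offsets[k] += step
            proposal = combined_information(pssms, offsets)
            d_info = proposal - current
            if d_info >= 0 or rng.random() < math.exp(d_info / t):
                current = proposal
                if current > best:
                    best = current
                    best_offsets = offsets.copy()
            else:
                offsets[k] -= step
    center = int(np.floor(np.median(best_offsets)))
    return best_offsets - center


def make_logo(aligned_cores: Sequence[str]) -> LogoData:
    """Logo data from a pooled stack of aligned cores.

    R_i = log2(20) + sum_a f_a,i log2 f_a,i (bits, no small-sample
    correction); letter heights h_a,i = f_a,i * R_i.
    """
    freqs = column_frequencies(aligned_cores, pseudocount=0.0)
    R = _info_bits(freqs)
    return LogoData(R=R, heights=freqs * R[:, None])


def logo_from_frequencies(freqs: np.ndarray) -> LogoData:
    """Logo data straight from a frequency matrix (rows sum to 1)."""
    freqs = np.asarray(freqs, dtype=np.float64)
    R = _info_bits(freqs)
    return LogoData(R=R, heights=freqs * R[:, None])


def log_odds_matrix(pssm: PSSM, background: Optional[np.ndarray] = None) -> np.ndarray:
    """Half-bit log-odds scores 2*log2(f/q) against the background."""
    q = BACKGROUND_FREQS if background is None else np.asarray(background, dtype=float)
    return 2.0 * np.log2(pssm.freqs / q[None, :])


@dataclass
class EnsembleLogo:
    """Combined motif representation of a whole ensemble."""

    logo: LogoData
    pssm: PSSM
    log_odds: np.ndarray
    offsets: np.ndarray            # per network, consensus register shifts
    per_network: list[PSSM]
    n_cores: int


def ensemble_logo(
    ensemble,
    n_background: int = 100_000,
    top_fraction: float = 0.01,
    max_shift: int = 4,
    seed: int = 0,
    skip_offset_correction: bool = False,
    schedule: Optional[AnnealSchedule] = None,
) -> EnsembleLogo:
    """Build the combined, offset-corrected motif logo of an ensemble.

    Background peptides of length motif_len + 2*flank_len are scored by
    every member network; per-network PSSMs over the top fraction are
    aligned by offset correction, each network's ``logo_offset`` is set,
    and the re-aligned cores are pooled into the combined logo and
    log-odds PSSM.  Re-aligned cores whose shifted window falls outside
    the source peptide are dropped.  With ``skip_offset_correction`` the
    ensemble's overall top-scoring cores are pooled unshifted.
    """
    m = ensemble.motif_len
    L = m + 2 * ensemble.flank_len
    background = generate_background_peptides(n_background, L, seed)
    all_offs, all_scores = _score_background(ensemble.networks, background)
    per_pssms = []
    per_cores = []
    for k in range(len(ensemble.networks)):
        picked = _top_cores(background, all_offs[k], all_scores[k], top_fraction, m)
        cores_k = [background[i][o : o + m] for i, o in picked]
        per_pssms.append(
            PSSM(
                freqs=column_frequencies(cores_k, pseudocount=PSEUDOCOUNT),
                n_cores=len(cores_k),
                pseudocount=PSEUDOCOUNT,
            )
        )
        per_cores.append(picked)

    if skip_offset_correction:
        # pool the ensemble's overall top fraction, unshifted: mean member
        # score, core by plurality of member choices
        mean_scores = all_scores.mean(axis=0)
        order = np.argsort(-mean_scores, kind="stable")
        k = math.ceil(top_fraction * n_background)
        cores = []
        for i in order[:k]:
            vals, counts = np.unique(all_offs[:, i], return_counts=True)
            off = int(vals[counts == counts.max()].min())
            cores.append(background[i][off : off + m])
        offsets = np.zeros(len(ensemble.networks), dtype=np.int64)
    else:
        offsets = offset_correction(per_pssms, max_shift=max_shift, schedule=schedule, seed=seed)
        for net, off in zip(ensemble.networks, offsets):
            net.logo_offset = int(off)
        cores = []
        for picked, off in zip(per_cores, offsets):
            for pep_i, raw_off in picked:
                start = raw_off - int(off)
                if 0 <= start <= L - m:
                    cores.append(background[pep_i][start : start + m])
        if not cores:
            # every shifted window left its source peptide (possible when
            # L == motif_len, e.g. flank 0: cores cannot move); fall back
            # to the unshifted per-network core pool
            warnings.warn(
                "offset-corrected cores have no overlap with the background "
                "windows; pooling unshifted cores instead"
            )
            offsets = np.zeros(len(ensemble.networks), dtype=np.int64)
            for net in ensemble.networks:
                net.logo_offset = 0
            cores = [
                background[pep_i][raw_off : raw_off + m]
                for picked in per_cores
                for pep_i, raw_off in picked
            ]
    freqs = column_frequencies(cores, pseudocount=PSEUDOCOUNT)
    pssm = PSSM(freqs=freqs, n_cores=len(cores), pseudocount=PSEUDOCOUNT)
    return EnsembleLogo(
        logo=make_logo(cores),
        pssm=pssm,
        log_odds=log_odds_matrix(pssm),
        offsets=offsets,
        per_network=per_pssms,
        n_cores=len(cores),
    )


def plot_logo(logo: LogoData, ax=None):
    """Thin matplotlib rendering of a logo (letter heights as stacked
    bars); correctness lives in the numeric LogoData, this is convenience."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(logo.R) + 1, 3))
    m = len(logo.R)
    for i in range(m):
        order = np.argsort(logo.heights[i])
        y = 0.0
        for a in order:
            h = logo.heights[i, a]
            if h <= 0:
                continue
            aa = logo.alphabet[a]
            ax.bar(
                i + 1, h, bottom=y, width=0.8,
                color=logo.colors.get(aa, "grey"), edgecolor="white", linewidth=0.3,
            )
            if h > 0.12:
                ax.text(i + 1, y + h / 2, aa, ha="center", va="center", fontsize=7)
            y += h
    ax.set_xlabel("motif position")
    ax.set_ylabel("bits")
    ax.set_xticks(range(1, m + 1))
    ax.set_ylim(0, LOG2_20)
    return ax
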