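"""Ground-truth synthetic datasets for end-to-end testing and examples.

Two generators emulate the statistical structure of the experimental data
the method is aimed at:

* a *planted-motif* set mimicking receptor-ligand binding (e.g. MHC class
  II): variable-length peptides drawn from the background composition,
  scored by the best window under a hidden position weight matrix with a
  few anchor positions, mapped affinely to [0, 1] and perturbed with
  Gaussian noise;
* a *cleavage* set mimicking protease digestion of a peptide microarray
  synthesised as constant flanks around a short random region (lysine
  excluded for chemistry reasons): peptides containing a cleavable
  arginine (not followed by proline) score in a high band, R-R pairs
  higher still, everything else in a low band.

Both are bit-for-bit reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER, BACKGROUND_FREQS
from .peptide_io import QuantPeptideDataset


@dataclass
class PlantedMotifSpec:
    """Specification of a planted quantitative motif dataset."""

    motif_len: int = 9
    anchor_positions: tuple[int, ...] = (0, 3, 8)
    anchor_preferences: tuple[dict, ...] = (
        {"F": 0.5, "Y": 0.3, "W": 0.2},
        {"D": 0.6, "E": 0.4},
        {"L": 0.5, "I": 0.3, "V": 0.2},
    )
    peptide_length_range: tuple[int, int] = (10, 16)
    n_peptides: int = 1500
    noise_sd: float = 0.05
    seed: int = 0
    #: weight of the anchor preference vs background at anchor positions
    anchor_strength: float = 0.9

    def __post_init__(self) -> None:
        if len(self.anchor_positions) != len(self.anchor_preferences):
            raise ValueError("one preference map per anchor position required")
        if any(not 0 <= a < self.motif_len for a in self.anchor_positions):
            raise ValueError("anchor positions must lie inside the motif")
        if self.peptide_length_range[0] < self.motif_len:
            raise ValueError("minimum peptide length must be >= motif_len")

    def true_pssm(self) -> np.ndarray:
        """The planted per-position frequency matrix (motif_len x 20)."""
        pssm = np.tile(BACKGROUND_FREQS, (self.motif_len, 1))
        for pos, prefs in zip(self.anchor_positions, self.anchor_preferences):
            row = (1.0 - self.anchor_strength) * BACKGROUND_FREQS.copy()
            for aa, w in prefs.items():
                row[AA_INDEX[aa]] += self.anchor_strength * w
            pssm[pos] = row / row.sum()
        return pssm


@dataclass
class PlantedMotifTruth:
    spec: PlantedMotifSpec
    pssm: np.ndarray
    core_offsets: np.ndarray     # per peptide, argmax offset
    clean_scores: np.ndarray     # targets before noise


def _loglik_best_window(codes: np.ndarray, log_pssm: np.ndarray) -> tuple[float, int]:
    m = log_pssm.shape[0]
    best, best_o = -np.inf, 0
    for o in range(len(codes) - m + 1):
        s = float(log_pssm[np.arange(m), codes[o : o + m]].sum())
        if s > best:
            best, best_o = s, o
    return best, best_o


def make_planted_motif_dataset(
    spec: PlantedMotifSpec,
) -> tuple[QuantPeptideDataset, PlantedMotifTruth]:
    """Generate a planted-motif dataset and its ground truth.

    Each peptide's clean score is the maximum over windows of the core
    log-likelihood under the planted PSSM, affinely mapped so the
    generated set spans [0, 1]; Gaussian noise (sd = spec.noise_sd) is
    then added and the result clipped back to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.peptide_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_peptides)
    pssm = spec.true_pssm()
    log_pssm = np.log2(pssm)
    peptides = []
    raw_scores = np.empty(spec.n_peptides)
    offsets = np.empty(spec.n_peptides, dtype=np.int64)
    letters = np.array(list(AA_ORDER))
    for i, L in enumerate(lengths):
        codes = rng.choice(20, size=int(L), p=BACKGROUND_FREQS)
        peptides.append("".join(letters[codes]))
        raw_scores[i], offsets[i] = _loglik_best_window(codes, log_pssm)
    span = raw_scores.max() - raw_scores.min()
    clean = (raw_scores - raw_scores.min()) / span
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.n_peptides)
    noisy = np.clip(noisy, 0.0, 1.0)
    dataset = QuantPeptideDataset(peptides=peptides, targets=list(noisy))
    truth = PlantedMotifTruth(
        spec=spec, pssm=pssm, core_offsets=offsets, clean_scores=clean
    )
    return dataset, truth


def make_cleavage_dataset(
    n_peptides: int = 5000,
    random_region_len: int = 5,
    flanks: tuple[str, str] = ("GAGA", "GAGA"),
    exclude_residues: str = "K",
    seed: int = 0,
) -> QuantPeptideDataset:
    """Generate a trypsin-style cleavage dataset.

    Peptides are flank + random region + flank, the random region drawn
    from the background composition with the excluded residues removed.
    Targets (seeded jitter within each band): peptides containing an R-R
    pair score in [0.97, 1.0]; peptides with any R not immediately
    followed by P score in [0.85, 0.97); everything else — no arginine,
    or arginine only in uncleavable R-P context — scores in [0, 0.1).
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    rng = np.random.default_rng(seed)
    keep = [i for i, aa in enumerate(AA_ORDER) if aa not in exclude_residues]
    freqs = BACKGROUND_FREQS[keep]
    freqs = freqs / freqs.sum()
    letters = np.array(list(AA_ORDER))[keep]
    peptides = []
    targets = []
    for _ in range(n_peptides):
        region = "".join(
            letters[rng.choice(len(keep), size=random_region_len, p=freqs)]
        )
        pep = flanks[0] + region + flanks[1]
        if "RR" in pep:
            t = rng.uniform(0.97, 1.0)
        elif any(
            pep[i] == "R" and (i + 1 == len(pep) or pep[i + 1] != "P")
            for i in range(len(pep))
        ):
            t = rng.uniform(0.85, 0.97)
        else:
            t = rng.uniform(0.0, 0.1)
        peptides.append(pep)
        targets.append(float(t))
    return QuantPeptideDataset(peptides=peptides, targets=targets)
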