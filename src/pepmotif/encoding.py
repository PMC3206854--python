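"""Numeric encoding of (peptide, core offset) pairs for the networks.

A candidate binding core of ``motif_len`` consecutive residues is encoded
residue-by-residue, either sparse (one-hot) or as BLOSUM62 rows scaled by
1/5 so that similar residues receive similar inputs.  Optional extra
features summarise the peptide flanking regions (PFR) outside the core —
their mean residue composition and a saturating length fraction per side —
and the overall peptide length through a logistic squashing centred at 15
residues.  The feature order is frozen (core, PFR composition N then C,
PFR lengths N then C, peptide length) so serialized models stay portable.

'X' encodes as the mean of the 20 residue vectors under either scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, BLOSUM62, peptides_to_codes

#: BLOSUM rows are divided by this to tame input magnitudes.
BLOSUM_SCALE = 5.0
#: centre of the logistic peptide-length feature
LENGTH_CENTER = 15.0
LENGTH_SLOPE = 2.0


def _scheme_matrix(scheme: str) -> np.ndarray:
    """21x20 encoding matrix (rows: A..Y then X)."""
    if scheme == "sparse":
        base = np.eye(20, dtype=np.float64)
    elif scheme == "blosum":
        base = BLOSUM62 / BLOSUM_SCALE
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    x_row = base.mean(axis=0, keepdims=True)
    return np.vstack([base, x_row])


_SCHEME_CACHE: dict[str, np.ndarray] = {}


def scheme_matrix(scheme: str) -> np.ndarray:
    if scheme not in _SCHEME_CACHE:
        _SCHEME_CACHE[scheme] = _scheme_matrix(scheme)
    return _SCHEME_CACHE[scheme]


@dataclass(frozen=True)
class EncodingConfig:
    scheme: str = "blosum"
    motif_len: int = 9
    flank_len: int = 0
    use_pfr_composition: bool = False
    use_pfr_length: bool = False
    use_peptide_length: bool = False

    def __post_init__(self) -> None:
        if self.motif_len < 1:
            raise ValueError("motif_len must be >= 1")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")
        scheme_matrix(self.scheme)  # validates the scheme name

    @property
    def input_dim(self) -> int:
        dim = self.motif_len * 20
        if self.use_pfr_composition:
            dim += 2 * 20
        if self.use_pfr_length:
            dim += 2
        if self.use_peptide_length:
            dim += 1
        return dim

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "motif_len": self.motif_len,
            "flank_len": self.flank_len,
            "use_pfr_composition": self.use_pfr_composition,
            "use_pfr_length": self.use_pfr_length,
            "use_peptide_length": self.use_peptide_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingConfig":
        return cls(**d)


def encode_residue(aa: str, scheme: str = "sparse") -> np.ndarray:
    """Encode a single residue as a vector of 20 reals."""
    mat = scheme_matrix(scheme)
    if aa == "X":
        return mat[20].copy()
    if aa not in AA_INDEX:
        raise ValueError(f"illegal residue {aa!r}")
    return mat[AA_INDEX[aa]].copy()


def peptide_length_feature(length: int) -> float:
    return 1.0 / (1.0 + np.exp((length - LENGTH_CENTER) / LENGTH_SLOPE))


@dataclass
class EncodedInstance:
    vector: np.ndarray
    core_offset: int


def encode_instance(peptide: str, core_offset: int, config: EncodingConfig) -> EncodedInstance:
    """Encode one (peptide, core offset) pair into an input vector."""
    L = len(peptide)
    m = config.motif_len
    if L < m:
        raise ValueError(f"peptide {peptide!r} shorter than motif length {m}")
    if not 0 <= core_offset <= L - m:
        raise ValueError(f"core offset {core_offset} out of range for {peptide!r}")
    mat = scheme_matrix(config.scheme)
    codes = peptides_to_codes([peptide])[0]
    parts = [mat[codes[core_offset : core_offset + m]].ravel()]
    if config.use_pfr_composition:
        for lo, hi in (
            (max(0, core_offset - config.flank_len), core_offset),
            (core_offset + m, min(L, core_offset + m + config.flank_len)),
        ):
            if hi > lo and config.flank_len > 0:
                parts.append(mat[codes[lo:hi]].mean(axis=0))
            else:
                parts.append(np.zeros(20))
    if config.use_pfr_length:
        n_flank = min(core_offset, config.flank_len)
        c_flank = min(L - m - core_offset, config.flank_len)
        if config.flank_len > 0:
            parts.append(np.array([n_flank / config.flank_len, c_flank / config.flank_len]))
        else:
            parts.append(np.zeros(2))
    if config.use_peptide_length:
        parts.append(np.array([peptide_length_feature(L)]))
    vec = np.concatenate(parts)
    assert vec.shape == (config.input_dim,)
    return EncodedInstance(vector=vec, core_offset=core_offset)


@dataclass
class BatchEncoding:
    """All core offsets of a list of peptides, encoded as one dense matrix.

    ``X[start[p]:start[p+1]]`` holds peptide ``p``'s offsets 0, 1, ... in
    order, so row ``start[p] + o`` is offset ``o``.
    """

    X: np.ndarray            # (total_offsets, input_dim) float64, C-contiguous
    start: np.ndarray        # (n_peptides + 1,) int64
    peptides: list[str]
    config: EncodingConfig

    @property
    def n_peptides(self) -> int:
        return len(self.start) - 1

    def rows_for(self, p: int) -> np.ndarray:
        return self.X[self.start[p] : self.start[p + 1]]


def encode_peptides(peptides: list[str], config: EncodingConfig) -> BatchEncoding:
    """Vectorized encoding of every core offset of every peptide.

    Peptides are grouped by length so each (length, offset) template is
    encoded with a single fancy-indexing operation; output rows are then
    scattered back to per-peptide contiguous blocks.
    """
    m = config.motif_len
    D = config.input_dim
    mat = scheme_matrix(config.scheme)
    codes_list = peptides_to_codes(peptides)
    lengths = np.array([len(p) for p in peptides])
    if (lengths < m).any():
        bad = peptides[int(np.argmax(lengths < m))]
        raise ValueError(f"peptide {bad!r} shorter than motif length {m}")
    n_off = lengths - m + 1
    start = np.zeros(len(peptides) + 1, dtype=np.int64)
    np.cumsum(n_off, out=start[1:])
    X = np.empty((int(start[-1]), D), dtype=np.float64)

    by_len: dict[int, list[int]] = {}
    for p, L in enumerate(lengths):
        by_len.setdefault(int(L), []).append(p)

    for L, members in by_len.items():
        codes = np.stack([codes_list[p] for p in members])  # (g, L)
        g = len(members)
        rows_base = np.array([start[p] for p in members])
        if config.use_peptide_length:
            len_feat = peptide_length_feature(L)
        for o in range(L - m + 1):
            block = np.empty((g, D), dtype=np.float64)
            col = 0
            core = mat[codes[:, o : o + m]].reshape(g, m * 20)
            block[:, col : col + m * 20] = core
            col += m * 20
            if config.use_pfr_composition:
                lo, hi = max(0, o - config.flank_len), o
                if hi > lo and config.flank_len > 0:
                    block[:, col : col + 20] = mat[codes[:, lo:hi]].mean(axis=1)
                else:
                    block[:, col : col + 20] = 0.0
                col += 20
                lo, hi = o + m, min(L, o + m + config.flank_len)
                if hi > lo and config.flank_len > 0:
                    block[:, col : col + 20] = mat[codes[:, lo:hi]].mean(axis=1)
                else:
                    block[:, col : col + 20] = 0.0
                col += 20
            if config.use_pfr_length:
                if config.flank_len > 0:
                    block[:, col] = min(o, config.flank_len) / config.flank_len
                    block[:, col + 1] = min(L - m - o, config.flank_len) / config.flank_len
                else:
                    block[:, col : col + 2] = 0.0
                col += 2
            if config.use_peptide_length:
                block[:, col] = len_feat
                col += 1
            X[rows_base + o] = block
    return BatchEncoding(X=X, start=start, peptides=list(peptides), config=config)
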