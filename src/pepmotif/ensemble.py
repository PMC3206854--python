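"""Cross-validated training, ensemble assembly and performance measures.

Training is organised as n-fold cross-validation: rescaling parameters are
fitted on each training portion only, a grid of (hidden size x random
seed) networks is trained per fold, and every record receives exactly one
cross-validated prediction from networks that never saw it.  Two
evaluation modes exist: *fast*, where the held-out fold doubles as the
stopping set, and *exhaustive*, a nested procedure where each remaining
fold takes a turn as stopping set and the held-out fold is predicted by
the average of the per-inner-step best networks.  The final model is the
top-N networks per fold ranked by stopping-set RMSE.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .encoding import EncodingConfig, encode_peptides
from .network import TrainSchedule, TrainedNetwork, score_batch, train_network
from .partition import CVPartition, build_partition
from .peptide_io import QuantPeptideDataset
from .preprocess import RescaleParams, apply_rescaler, fit_rescaler

N_BOOTSTRAP = 100


@dataclass
class CVConfig:
    folds: int = 5
    method: str = "random"  # random | hobohm1 | common_motif
    threshold: float = 0.8
    representatives_only: bool = False
    trim_flanks: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CVConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    """Every user-settable training parameter.

    The motif length is the one required parameter; everything else
    defaults to the server-style settings (5 folds, 5 seeds, 3 hidden
    neurons, linear rescaling).
    """

    motif_lengths: list[int]
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    hidden_sizes: list[int] = field(default_factory=lambda: [3])
    n_seeds: int = 5
    cv: CVConfig = field(default_factory=CVConfig)
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    eval_mode: str = "fast"  # fast | exhaustive
    top_n: int = 5
    auc_threshold: float = 0.5
    rescale_mode: str = "linear"
    collapse_duplicates: bool = False

    def __post_init__(self) -> None:
        if not self.motif_lengths:
            raise ValueError("motif_lengths must be non-empty")
        if any(m < 1 for m in self.motif_lengths):
            raise ValueError("motif lengths must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.eval_mode not in ("fast", "exhaustive"):
            raise ValueError(f"unknown eval_mode {self.eval_mode!r}")

    def encoding_for(self, motif_len: int) -> EncodingConfig:
        return dataclasses.replace(self.encoding, motif_len=motif_len)

    def to_dict(self) -> dict:
        return {
            "motif_lengths": list(self.motif_lengths),
            "encoding": self.encoding.to_dict(),
            "hidden_sizes": list(self.hidden_sizes),
            "n_seeds": self.n_seeds,
            "cv": self.cv.to_dict(),
            "schedule": self.schedule.to_dict(),
            "eval_mode": self.eval_mode,
            "top_n": self.top_n,
            "auc_threshold": self.auc_threshold,
            "rescale_mode": self.rescale_mode,
            "collapse_duplicates": self.collapse_duplicates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["encoding"] = EncodingConfig.from_dict(d["encoding"])
        d["cv"] = CVConfig.from_dict(d["cv"])
        d["schedule"] = TrainSchedule.from_dict(d["schedule"])
        return cls(**d)


@dataclass
class CVResult:
    """Outcome of one cross-validation run at a fixed motif length."""

    motif_len: int
    partition: CVPartition
    fold_networks: list[list[TrainedNetwork]]   # candidates for the final ensemble
    predictions: np.ndarray                     # per record, NaN if disregarded
    core_offsets: np.ndarray                    # per record, -1 if disregarded
    observed_rescaled: np.ndarray               # per record, NaN if disregarded
    fold_rescalers: list[RescaleParams]
    n_networks_trained: int

    @property
    def retained(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.predictions))

    def rmse(self) -> float:
        idx = self.retained
        return float(
            np.sqrt(np.mean((self.predictions[idx] - self.observed_rescaled[idx]) ** 2))
        )


@dataclass
class Ensemble:
    """The serialisable unit: the selected networks plus everything needed
    to score new peptides (encoding config travels inside each network,
    rescaling parameters for reporting observed values on the same scale).
    """

    networks: list[TrainedNetwork]
    rescale_params: Optional[RescaleParams]
    train_config: Optional[TrainConfig] = None

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("ensemble must contain at least one network")
        lens = {n.config.motif_len for n in self.networks}
        if len(lens) != 1:
            raise ValueError("all ensemble networks must share one motif length")

    @property
    def motif_len(self) -> int:
        return self.networks[0].config.motif_len

    @property
    def flank_len(self) -> int:
        return self.networks[0].config.flank_len

    def to_dict(self) -> dict:
        return {
            "networks": [n.to_dict() for n in self.networks],
            "rescale_params": None
            if self.rescale_params is None
            else self.rescale_params.to_dict(),
            "train_config": None
            if self.train_config is None
            else self.train_config.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ensemble":
        return cls(
            networks=[TrainedNetwork.from_dict(n) for n in d["networks"]],
            rescale_params=None
            if d.get("rescale_params") is None
            else RescaleParams.from_dict(d["rescale_params"]),
            train_config=None
            if d.get("train_config") is None
            else TrainConfig.from_dict(d["train_config"]),
        )

    def predict(self, peptides: Sequence[str]) -> pd.DataFrame:
        return predict(self, peptides)

    def scan_fasta(self, records) -> pd.DataFrame:
        return scan_fasta(self, records)


# ---------------------------------------------------------------------------


def collapse_duplicate_peptides(dataset: QuantPeptideDataset) -> QuantPeptideDataset:
    """Collapse duplicate peptides to the mean of their measurements."""
    if not dataset.has_targets:
        seen = dict.fromkeys(dataset.peptides)
        return QuantPeptideDataset(peptides=list(seen))
    sums: dict[str, list[float]] = {}
    order: list[str] = []
    for pep, t in zip(dataset.peptides, dataset.targets):
        if pep not in sums:
            sums[pep] = []
            order.append(pep)
        sums[pep].append(t)
    return QuantPeptideDataset(
        peptides=order, targets=[float(np.mean(sums[p])) for p in order]
    )


def _net_seed(base: int, fold: int, inner: int, arch_i: int, seed_i: int) -> int:
    return (base * 1_000_003 + fold * 9_973 + (inner + 1) * 389 + arch_i * 37 + seed_i) % (
        2**31
    )


def _plurality_offset(raw_offsets: np.ndarray, logo_offsets: np.ndarray, max_offset: int) -> int:
    """Combine member core choices: shift each by its network's logo offset,
    take the most frequent value (ties -> smallest), clip into range."""
    corrected = raw_offsets - logo_offsets
    vals, counts = np.unique(corrected, return_counts=True)
    winner = int(vals[counts == counts.max()].min())
    return int(np.clip(winner, 0, max_offset))


def _train_grid(
    peptides_tr,
    targets_tr,
    peptides_stop,
    targets_stop,
    config: TrainConfig,
    encoding: EncodingConfig,
    fold: int,
    inner: int,
    seed: int,
) -> list[TrainedNetwork]:
    enc_tr = encode_peptides(peptides_tr, encoding)
    enc_stop = encode_peptides(peptides_stop, encoding)
    nets = []
    for arch_i, n_hidden in enumerate(config.hidden_sizes):
        for seed_i in range(config.n_seeds):
            net = train_network(
                peptides_tr,
                targets_tr,
                config.schedule,
                encoding,
                n_hidden,
                _net_seed(seed, fold, inner, arch_i, seed_i),
                stop_peptides=peptides_stop,
                stop_targets=targets_stop,
                train_encoding=enc_tr,
                stop_encoding=enc_stop,
            )
            net.fold = fold
            nets.append(net)
    return nets


def run_cross_validation(
    dataset: QuantPeptideDataset,
    config: TrainConfig,
    motif_len: int,
    partition: CVPartition,
    seed: int = 0,
) -> CVResult:
    """Run one full cross-validation at a fixed motif length.

    Every retained record is predicted exactly once, by networks whose
    training folds excluded it.
    """
    if not dataset.has_targets:
        raise ValueError("cross-validation needs measurements")
    encoding = config.encoding_for(motif_len)
    peptides = dataset.peptides
    raw = np.asarray(dataset.targets, dtype=float)
    n = len(peptides)
    predictions = np.full(n, np.nan)
    core_offsets = np.full(n, -1, dtype=np.int64)
    observed = np.full(n, np.nan)
    fold_networks: list[list[TrainedNetwork]] = []
    fold_rescalers: list[RescaleParams] = []
    n_trained = 0

    for f in range(partition.n_folds):
        test_idx = partition.fold_indices(f)
        train_idx = np.array(
            [i for i in partition.retained if partition.fold_of[i] != f], dtype=np.int64
        )
        if len(test_idx) < 1:
            raise ValueError(f"fold {f} is empty")
        rescaler = fit_rescaler(raw[train_idx], config.rescale_mode)
        fold_rescalers.append(rescaler)
        t_train = apply_rescaler(rescaler, raw[train_idx])
        t_test = apply_rescaler(rescaler, raw[test_idx])
        observed[test_idx] = t_test
        peps_tr = [peptides[i] for i in train_idx]
        peps_te = [peptides[i] for i in test_idx]

        if config.eval_mode == "fast":
            nets = _train_grid(
                peps_tr, t_train, peps_te, t_test, config, encoding, f, -1, seed
            )
            n_trained += len(nets)
            candidates = nets
        else:
            inner_folds = [g for g in range(partition.n_folds) if g != f]
            candidates = []
            for g in inner_folds:
                stop_idx = np.array(
                    [i for i in train_idx if partition.fold_of[i] == g], dtype=np.int64
                )
                inner_tr_idx = np.array(
                    [i for i in train_idx if partition.fold_of[i] != g], dtype=np.int64
                )
                inner_label = g
                if len(inner_tr_idx) == 0:
                    # 2-fold degenerate case: the remainder is a single fold,
                    # which must serve as both training and stopping set; the
                    # step then coincides with the fast-mode step (same seeds)
                    inner_tr_idx = stop_idx
                    inner_label = -1
                t_inner = apply_rescaler(rescaler, raw[inner_tr_idx])
                t_stop = apply_rescaler(rescaler, raw[stop_idx])
                nets = _train_grid(
                    [peptides[i] for i in inner_tr_idx],
                    t_inner,
                    [peptides[i] for i in stop_idx],
                    t_stop,
                    config,
                    encoding,
                    f,
                    inner_label,
                    seed,
                )
                n_trained += len(nets)
                rmses = [net.stop_rmse for net in nets]
                best = int(np.argmin(rmses))
                candidates.append(nets[best])

        fold_networks.append(candidates)
        enc_te = encode_peptides(peps_te, encoding)
        member_offs = np.stack([score_batch(net, enc_te)[0] for net in candidates])
        member_scores = np.stack([score_batch(net, enc_te)[1] for net in candidates])
        predictions[test_idx] = member_scores.mean(axis=0)
        logo_offs = np.zeros(len(candidates), dtype=np.int64)
        for j, i in enumerate(test_idx):
            core_offsets[i] = _plurality_offset(
                member_offs[:, j], logo_offs, len(peptides[i]) - motif_len
            )

    return CVResult(
        motif_len=motif_len,
        partition=partition,
        fold_networks=fold_networks,
        predictions=predictions,
        core_offsets=core_offsets,
        observed_rescaled=observed,
        fold_rescalers=fold_rescalers,
        n_networks_trained=n_trained,
    )


def bootstrap_rmse(
    predictions: np.ndarray, observations: np.ndarray, seed: int, n_boot: int = N_BOOTSTRAP
) -> tuple[float, float]:
    """Bootstrap mean and standard error of the RMSE over prediction pairs."""
    rng = np.random.default_rng(seed)
    n = len(predictions)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = np.sqrt(np.mean((predictions[idx] - observations[idx]) ** 2))
    return float(vals.mean()), float(vals.std(ddof=1))


def scan_motif_lengths(
    dataset: QuantPeptideDataset,
    config: TrainConfig,
    partition: Optional[CVPartition] = None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame, dict[int, CVResult]]:
    """Cross-validate every candidate motif length and pick the best.

    The chosen length is the argmin of the cross-validated RMSE (ties go
    to the shorter length).  The returned table also carries a bootstrap
    mean and standard error of each RMSE so a flat length dependence can
    be recognised.  Candidate lengths longer than the shortest peptide are
    skipped with a warning.
    """
    min_pep = min(len(p) for p in dataset.peptides)
    lengths = sorted(set(config.motif_lengths))
    usable = []
    for m in lengths:
        if m > min_pep:
            warnings.warn(
                f"motif length {m} exceeds the shortest peptide ({min_pep}); skipped"
            )
        else:
            usable.append(m)
    if not usable:
        raise ValueError("no candidate motif length fits the data")
    if partition is None:
        partition = build_partition(
            dataset.peptides,
            config.cv.folds,
            method=config.cv.method,
            threshold=config.cv.threshold,
            representatives_only=config.cv.representatives_only,
            trim_flanks=config.cv.trim_flanks,
            motif_min_len=min(usable),
            seed=seed,
        )
    rows = []
    results: dict[int, CVResult] = {}
    for m in usable:
        cv = run_cross_validation(dataset, config, m, partition, seed=seed)
        results[m] = cv
        idx = cv.retained
        bmean, bse = bootstrap_rmse(
            cv.predictions[idx], cv.observed_rescaled[idx], seed=seed + m
        )
        rows.append(
            {"motif_len": m, "rmse": cv.rmse(), "boot_mean": bmean, "boot_se": bse}
        )
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["rmse", "motif_len"]).iloc[0]
    return int(best_row["motif_len"]), table, results


def select_final_ensemble(
    cv_result: CVResult,
    top_n: int,
    rescale_params: Optional[RescaleParams] = None,
    train_config: Optional[TrainConfig] = None,
) -> Ensemble:
    """Keep the ``top_n`` networks per fold, ranked by stopping-set RMSE."""
    selected: list[TrainedNetwork] = []
    for nets in cv_result.fold_networks:
        rmses = np.array(
            [np.inf if n.stop_rmse is None else n.stop_rmse for n in nets]
        )
        order = np.argsort(rmses, kind="stable")
        selected.extend(nets[i] for i in order[:top_n])
    return Ensemble(
        networks=selected, rescale_params=rescale_params, train_config=train_config
    )


def predict(ensemble: Ensemble, peptides: Sequence[str]) -> pd.DataFrame:
    """Score peptides with the ensemble.

    The score is the mean over member networks of each member's own
    best-core score; the reported core offset is the most frequent
    member choice after correcting each member's register by its logo
    offset (ties -> smallest).  Peptides shorter than the motif get an
    error entry rather than failing the whole call.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide list")
    m = ensemble.motif_len
    rows: list[dict] = []
    valid = [i for i, p in enumerate(peptides) if len(p) >= m]
    results: dict[int, tuple[float, int]] = {}
    if valid:
        enc = encode_peptides([peptides[i] for i in valid], ensemble.networks[0].config)
        member_offs = np.stack([score_batch(net, enc)[0] for net in ensemble.networks])
        member_scores = np.stack([score_batch(net, enc)[1] for net in ensemble.networks])
        mean_scores = member_scores.mean(axis=0)
        logo_offs = np.array([net.logo_offset for net in ensemble.networks], dtype=np.int64)
        for j, i in enumerate(valid):
            off = _plurality_offset(
                member_offs[:, j], logo_offs, len(peptides[i]) - m
            )
            results[i] = (float(mean_scores[j]), off)
    for i, pep in enumerate(peptides):
        if i in results:
            score, off = results[i]
            rows.append(
                {
                    "peptide": pep,
                    "score": score,
                    "core_offset": off,
                    "core": pep[off : off + m],
                    "error": None,
                }
            )
        else:
            rows.append(
                {
                    "peptide": pep,
                    "score": np.nan,
                    "core_offset": -1,
                    "core": "",
                    "error": f"peptide shorter than motif length {m}",
                }
            )
    return pd.DataFrame(rows)


def scan_fasta(ensemble: Ensemble, records) -> pd.DataFrame:
    """Cut proteins into overlapping windows and rank them by score.

    Window length is L = motif_len + 2*flank_len, stepped one residue at a
    time; start positions are 1-based.  Records shorter than L contribute
    their full sequence as a single window when it still fits the motif,
    and are skipped with a warning otherwise.  Output is sorted by
    descending score.
    """
    L = ensemble.motif_len + 2 * ensemble.flank_len
    windows: list[tuple[str, int, str]] = []
    for rec in records:
        seq = rec.sequence
        if len(seq) >= L:
            for s in range(len(seq) - L + 1):
                windows.append((rec.id, s + 1, seq[s : s + L]))
        elif len(seq) >= ensemble.motif_len:
            windows.append((rec.id, 1, seq))
        else:
            warnings.warn(
                f"record {rec.id!r} shorter than the motif length; skipped"
            )
    if not windows:
        return pd.DataFrame(
            columns=["record", "start", "peptide", "score", "core_offset", "core"]
        )
    preds = predict(ensemble, [w[2] for w in windows])
    out = pd.DataFrame(
        {
            "record": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "peptide": preds["peptide"],
            "score": preds["score"],
            "core_offset": preds["core_offset"],
            "core": preds["core"],
        }
    )
    return out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def evaluate(predictions, observations, auc_threshold: float = 0.5) -> dict:
    """Pearson r, Spearman rho, RMSE and ROC-AUC between predictions and
    observations (positives: observation > threshold on the rescaled
    scale).  Degenerate cases yield None entries with a warning rather
    than an exception.
    """
    pred = np.asarray(list(predictions), dtype=float)
    obs = np.asarray(list(observations), dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lists differ in length")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs to evaluate")
    out = {
        "n": int(pred.size),
        "rmse": float(np.sqrt(np.mean((pred - obs) ** 2))),
        "pearson": None,
        "spearman": None,
        "auc": None,
    }
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        warnings.warn("zero variance: correlations undefined")
    else:
        out["pearson"] = float(sps.pearsonr(obs, pred)[0])
        out["spearman"] = float(sps.spearmanr(obs, pred)[0])
    labels = (obs > auc_threshold).astype(int)
    if labels.min() == labels.max():
        warnings.warn("all observations fall in one class: AUC undefined")
    else:
        out["auc"] = float(roc_auc_score(labels, pred))
    return out
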