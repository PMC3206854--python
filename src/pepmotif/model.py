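"""Model / Results front end.

`MotifModel` holds the data and the training configuration; `fit()` runs
the whole pipeline (partitioning, per-length cross-validation, final
ensemble selection, offset-corrected logo) and returns a `MotifResults`
carrying the cross-validated predictions, the performance measures, the
motif representations and a text `summary()`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .encoding import EncodingConfig
from .ensemble import (
    CVConfig,
    CVResult,
    Ensemble,
    TrainConfig,
    collapse_duplicate_peptides,
    evaluate,
    run_cross_validation,
    scan_motif_lengths,
    select_final_ensemble,
)
from .motif_logo import AnnealSchedule, EnsembleLogo, ensemble_logo
from .network import TrainSchedule
from .partition import build_partition
from .peptide_io import (
    QuantPeptideDataset,
    read_peptide_table,
    save_model,
    write_pssm_text,
)
from .preprocess import fit_rescaler


@dataclass
class LogoConfig:
    n_background: int = 100_000
    top_fraction: float = 0.01
    max_shift: int = 4
    skip_offset_correction: bool = False


class MotifModel:
    """Quantitative peptide motif model.

    Parameters
    ----------
    peptides, targets
        The training data: peptide strings and one real measurement each.
    motif_lengths
        The required parameter — a single length or a list of candidate
        lengths to scan (the length with the lowest cross-validated RMSE
        is kept).
    config
        Full `TrainConfig`; when given, `motif_lengths` and the keyword
        shortcuts are ignored.
    **options
        Shortcuts for the common `TrainConfig` fields: `scheme`,
        `flank_len`, `use_pfr_composition`, `use_pfr_length`,
        `use_peptide_length`, `hidden_sizes`, `n_seeds`, `folds`,
        `cv_method`, `cv_threshold`, `representatives_only`,
        `trim_flanks`, `iterations`, `learning_rate`,
        `stop_on_best_test`, `eval_mode`, `top_n`, `auc_threshold`,
        `rescale_mode`, `collapse_duplicates`.
    """

    def __init__(
        self,
        peptides: Sequence[str],
        targets: Sequence[float],
        motif_lengths: Union[int, Sequence[int], None] = None,
        config: Optional[TrainConfig] = None,
        logo: Optional[LogoConfig] = None,
        **options,
    ) -> None:
        self.dataset = QuantPeptideDataset(
            peptides=list(peptides), targets=list(targets)
        )
        if config is None:
            if motif_lengths is None:
                raise ValueError(
                    "motif_lengths is required (the one critical parameter)"
                )
            if isinstance(motif_lengths, int):
                motif_lengths = [motif_lengths]
            config = _config_from_options(list(motif_lengths), options)
        elif options:
            raise TypeError(f"unexpected options with explicit config: {options}")
        self.config = config
        self.logo_config = logo or LogoConfig()

    # ------------------------------------------------------------------
    @classmethod
    def from_table(cls, path_or_stream, **kwargs) -> "MotifModel":
        ds = read_peptide_table(path_or_stream)
        if not ds.has_targets:
            raise ValueError("training table must carry measurement values")
        return cls(ds.peptides, ds.targets, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, peptide_col: str = "peptide",
        target_col: str = "target", **kwargs,
    ) -> "MotifModel":
        return cls(df[peptide_col].tolist(), df[target_col].tolist(), **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, build_logo: bool = True) -> "MotifResults":
        """Run the full training pipeline; deterministic given ``seed``."""
        config = self.config
        dataset = self.dataset
        if config.collapse_duplicates:
            dataset = collapse_duplicate_peptides(dataset)
        partition = build_partition(
            dataset.peptides,
            config.cv.folds,
            method=config.cv.method,
            threshold=config.cv.threshold,
            representatives_only=config.cv.representatives_only,
            trim_flanks=config.cv.trim_flanks,
            motif_min_len=min(config.motif_lengths),
            seed=seed,
        )
        best_len, length_table, cv_by_len = scan_motif_lengths(
            dataset, config, partition=partition, seed=seed
        )
        cv = cv_by_len[best_len]
        idx = cv.retained
        metrics = evaluate(
            cv.predictions[idx], cv.observed_rescaled[idx], config.auc_threshold
        )
        rescale_params = fit_rescaler(dataset.targets, config.rescale_mode)
        final_config = dataclasses.replace(config, motif_lengths=[best_len])
        ens = select_final_ensemble(
            cv, config.top_n, rescale_params, final_config
        )
        logo = None
        if build_logo:
            lc = self.logo_config
            logo = ensemble_logo(
                ens,
                n_background=lc.n_background,
                top_fraction=lc.top_fraction,
                max_shift=lc.max_shift,
                seed=seed,
                skip_offset_correction=lc.skip_offset_correction,
            )
        cv_predictions = pd.DataFrame(
            {
                "peptide": [dataset.peptides[i] for i in idx],
                "observed": [dataset.targets[i] for i in idx],
                "observed_rescaled": cv.observed_rescaled[idx],
                "predicted": cv.predictions[idx],
                "core_offset": cv.core_offsets[idx],
                "core": [
                    dataset.peptides[i][
                        cv.core_offsets[i] : cv.core_offsets[i] + best_len
                    ]
                    for i in idx
                ],
            }
        )
        return MotifResults(
            model=self,
            ensemble=ens,
            motif_len=best_len,
            cv_result=cv,
            cv_predictions=cv_predictions,
            metrics=metrics,
            rmse_by_length=length_table,
            motif=logo,
            seed=seed,
        )


def _config_from_options(motif_lengths: list[int], opts: dict) -> TrainConfig:
    opts = dict(opts)
    enc = EncodingConfig(
        scheme=opts.pop("scheme", "blosum"),
        motif_len=motif_lengths[0],
        flank_len=opts.pop("flank_len", 0),
        use_pfr_composition=opts.pop("use_pfr_composition", False),
        use_pfr_length=opts.pop("use_pfr_length", False),
        use_peptide_length=opts.pop("use_peptide_length", False),
    )
    cv = CVConfig(
        folds=opts.pop("folds", 5),
        method=opts.pop("cv_method", "random"),
        threshold=opts.pop("cv_threshold", 0.8),
        representatives_only=opts.pop("representatives_only", False),
        trim_flanks=opts.pop("trim_flanks", False),
    )
    schedule = TrainSchedule(
        n_iterations=opts.pop("iterations", 500),
        learning_rate=opts.pop("learning_rate", 0.05),
        stop_on_best_test=opts.pop("stop_on_best_test", False),
    )
    config = TrainConfig(
        motif_lengths=motif_lengths,
        encoding=enc,
        hidden_sizes=list(opts.pop("hidden_sizes", [3])),
        n_seeds=opts.pop("n_seeds", 5),
        cv=cv,
        schedule=schedule,
        eval_mode=opts.pop("eval_mode", "fast"),
        top_n=opts.pop("top_n", 5),
        auc_threshold=opts.pop("auc_threshold", 0.5),
        rescale_mode=opts.pop("rescale_mode", "linear"),
        collapse_duplicates=opts.pop("collapse_duplicates", False),
    )
    if opts:
        raise TypeError(f"unknown options: {sorted(opts)}")
    return config


@dataclass
class MotifResults:
    """Everything `MotifModel.fit` produces."""

    model: MotifModel
    ensemble: Ensemble
    motif_len: int
    cv_result: CVResult
    cv_predictions: pd.DataFrame
    metrics: dict
    rmse_by_length: pd.DataFrame
    motif: Optional[EnsembleLogo]
    seed: int

    # ------------------------------------------------------------------
    def predict(self, peptides: Sequence[str]) -> pd.DataFrame:
        return self.ensemble.predict(peptides)

    def scan_fasta(self, records) -> pd.DataFrame:
        return self.ensemble.scan_fasta(records)

    def save(self, path) -> None:
        save_model(self.ensemble, path)

    @property
    def logo(self):
        return None if self.motif is None else self.motif.logo

    @property
    def pssm(self):
        return None if self.motif is None else self.motif.pssm

    def log_odds_text(self) -> str:
        if self.motif is None:
            raise ValueError("fit was run without logo construction")
        return write_pssm_text(
            self.motif.log_odds,
            header=(
                f"log-odds PSSM, half-bit units, motif length {self.motif_len}, "
                f"{self.motif.n_cores} aligned cores"
            ),
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        m = self.metrics
        cfg = self.model.config
        fmt = lambda v: "   n/a" if v is None else f"{v:6.3f}"
        lines = [
            "      Quantitative peptide motif discovery — fit summary",
            "=" * 62,
            f"No. peptides:        {len(self.model.dataset):6d}"
            f"    Motif length:      {self.motif_len:4d}",
            f"CV folds:            {cfg.cv.folds:6d}"
            f"    Partitioning:  {cfg.cv.method:>8s}",
            f"Hidden sizes:    {str(cfg.hidden_sizes):>10s}"
            f"    Seeds/arch:        {cfg.n_seeds:4d}",
            f"Epochs:              {cfg.schedule.n_iterations:6d}"
            f"    Encoding:      {cfg.encoding.scheme:>8s}",
            f"Eval mode:       {cfg.eval_mode:>10s}"
            f"    Ensemble size:     {len(self.ensemble.networks):4d}",
            "-" * 62,
            "Cross-validated performance (rescaled scale)",
            f"  RMSE:     {fmt(m['rmse'])}",
            f"  Pearson:  {fmt(m['pearson'])}",
            f"  Spearman: {fmt(m['spearman'])}",
            f"  ROC-AUC:  {fmt(m['auc'])}   (threshold {cfg.auc_threshold})",
        ]
        if len(self.rmse_by_length) > 1:
            lines.append("-" * 62)
            lines.append("RMSE by motif length (bootstrap mean ± SE)")
            for _, row in self.rmse_by_length.iterrows():
                marker = " <- selected" if int(row["motif_len"]) == self.motif_len else ""
                lines.append(
                    f"  {int(row['motif_len']):3d}: {row['rmse']:.4f} "
                    f"({row['boot_mean']:.4f} ± {row['boot_se']:.4f}){marker}"
                )
        if self.motif is not None:
            lines.append("-" * 62)
            top = np.argsort(-self.logo.R)[:3] + 1
            lines.append(
                "Motif information content per position (bits): "
                + " ".join(f"{v:.2f}" for v in self.logo.R)
            )
            lines.append(
                f"Most informative positions: {', '.join(str(p) for p in sorted(top))}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)
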