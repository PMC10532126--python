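"""Model/Results facade over the two-pathway respiratory-rate regressor.

`RespiratoryRateModel` is built from data (a cohort of thermal sequences,
or pre-cut clip pairs) plus the architecture/training configuration;
``fit()`` trains the network and returns a `RespiratoryRateResults` object
carrying the trained network, the loss trace, held-out diagnostics and a
``summary()`` table.  Cross-validation and plotting hang off these objects.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from .losses import rmse_metric
from .net import NetConfig, build_model, predict_rr, save_model
from .simulate import ThermalSequence
from .train import (
    TrainConfig, EvalReport, cohort_to_clips, cross_validate, derive_seeds,
    kfold_split, train,
)
from .windows import ClipPair, WindowSpec, sequence_to_clips

__all__ = ["RespiratoryRateModel", "RespiratoryRateResults"]


class RespiratoryRateModel:
    """A respiratory-rate regression model bound to its training data.

    Parameters
    ----------
    cohort
        Thermal sequences used for fitting.  A held-out validation share is
        split off by subject (never by recording) according to
        ``val_fraction``.
    config
        Full training configuration (architecture, window geometry, loss,
        schedule).  Defaults to the package's best-known configuration.
    val_fraction
        Fraction of subjects reserved for held-out diagnostics.
    """

    def __init__(
        self,
        cohort: list[ThermalSequence],
        config: TrainConfig | None = None,
        val_fraction: float = 0.2,
    ):
        if not cohort:
            raise ValueError("empty cohort")
        self.cohort = cohort
        self.config = config or TrainConfig()
        if not 0.0 <= val_fraction < 1.0:
            raise ValueError(f"val_fraction must be in [0, 1), got {val_fraction}")
        self.val_fraction = val_fraction

    @classmethod
    def from_clips(
        cls,
        train_clips: list[ClipPair],
        config: TrainConfig | None = None,
        val_clips: list[ClipPair] | None = None,
    ) -> "RespiratoryRateModel":
        """Alternative constructor from pre-cut clip pairs."""
        obj = cls.__new__(cls)
        obj.cohort = None
        obj.config = config or TrainConfig()
        obj.val_fraction = 0.0
        obj._train_clips = train_clips
        obj._val_clips = val_clips or []
        return obj

    def _split_clips(self) -> tuple[list[ClipPair], list[ClipPair]]:
        if getattr(self, "_train_clips", None) is not None:
            return self._train_clips, self._val_clips
        cfg = self.config
        clips = cohort_to_clips(self.cohort, cfg.window, cfg.net.alpha, cfg.net.beta)
        subjects = sorted({s.subject_id for s in self.cohort})
        n_val = int(round(self.val_fraction * len(subjects)))
        if n_val == 0:
            return clips, []
        seeds = derive_seeds(cfg.seed)
        rng = np.random.default_rng(seeds["folds"])
        val_subjects = set(
            np.asarray(subjects)[rng.permutation(len(subjects))[:n_val]].tolist()
        )
        train_clips = [c for c in clips if c.subject_id not in val_subjects]
        val_clips = [c for c in clips if c.subject_id in val_subjects]
        return train_clips, val_clips

    def fit(self, seed: int | None = None) -> "RespiratoryRateResults":
        """Train the network and return a results object."""
        cfg = self.config
        if seed is not None:
            from dataclasses import replace
            cfg = replace(cfg, seed=seed)
        train_clips, val_clips = self._split_clips()
        seeds = derive_seeds(cfg.seed)
        network = build_model(cfg.net, seed=seeds["weights"])
        network, trace = train(network, train_clips, cfg, val_clips=val_clips or None)
        return RespiratoryRateResults(self, network, trace, train_clips, val_clips, cfg)

    def cross_validate(self, k: int = 5) -> EvalReport:
        """Subject-grouped k-fold cross-validation on the bound cohort."""
        if self.cohort is None:
            raise ValueError("cross_validate requires a cohort-backed model")
        return cross_validate(self.cohort, k, self.config)


class RespiratoryRateResults:
    """Fitted-model container: trained network, traces, diagnostics."""

    def __init__(self, model, network, trace, train_clips, val_clips, config):
        self.model = model
        self.network = network
        self.trace = trace
        self.config = config
        self._train_clips = train_clips
        self._val_clips = val_clips
        preds = predict_rr(network, train_clips)
        self.train_rmse, self.train_spread = rmse_metric(
            preds, [c.label_rr for c in train_clips]
        )
        if val_clips:
            vpreds = predict_rr(network, val_clips)
            self.val_rmse, self.val_spread = rmse_metric(
                vpreds, [c.label_rr for c in val_clips]
            )
        else:
            self.val_rmse = self.val_spread = None

    # -- prediction --------------------------------------------------------

    def predict(self, data) -> np.ndarray:
        """Predict RR (bpm) for clip pairs or thermal sequences.

        For a sequence, every window is predicted and the mean returned, so
        the output has one value per input sequence.
        """
        if isinstance(data, ThermalSequence):
            data = [data]
        if data and isinstance(data[0], ThermalSequence):
            cfg = self.config
            out = []
            for seq in data:
                clips = sequence_to_clips(seq, cfg.window, cfg.net.alpha, cfg.net.beta)
                if not clips:
                    raise ValueError(
                        f"sequence {seq.subject_id} shorter than one window"
                    )
                out.append(float(np.mean(predict_rr(self.network, clips))))
            return np.asarray(out)
        return predict_rr(self.network, data)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of fit and diagnostics."""
        cfg = self.config
        lines = [
            "Respiratory-rate regression results",
            "=" * 51,
            f"{'backbone':<28}{cfg.net.backbone:>23}",
            f"{'stem/residual spatial k':<28}"
            f"{f'{cfg.net.stem_spatial_k}/{cfg.net.residual_spatial_k}':>23}",
            f"{'fusion kernel (t)':<28}{cfg.net.fusion_kernel_t:>23}",
            f"{'alpha / beta':<28}{f'{cfg.net.alpha}/{cfg.net.beta}':>23}",
            f"{'window length (frames)':<28}{cfg.net.window_len:>23}",
            f"{'width multiplier':<28}{cfg.net.width_multiplier:>23.4g}",
            f"{'parameters':<28}{self.network.n_parameters():>23,}",
            f"{'loss':<28}{f'{cfg.loss.name}/{cfg.loss.reduction}':>23}",
            f"{'epochs (warmup)':<28}{f'{cfg.epochs} ({cfg.warmup_epochs})':>23}",
            f"{'training clips':<28}{len(self._train_clips):>23}",
            "-" * 51,
            f"{'final training loss':<28}{self.trace['epoch_loss'][-1]:>23.4f}"
            if self.trace["epoch_loss"] else f"{'final training loss':<28}{'n/a':>23}",
            f"{'training RMSE (bpm)':<28}{self.train_rmse:>23.3f}",
        ]
        if self.val_rmse is not None:
            lines.append(
                f"{'held-out RMSE (bpm)':<28}"
                f"{f'{self.val_rmse:.3f} +/- {self.val_spread:.3f}':>23}"
            )
        lines.append("=" * 51)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training-loss (and validation RMSE) trace plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["epoch_loss"], label="training loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel(f"{self.config.loss.name} loss")
        if self.trace.get("val_rmse"):
            ax2 = ax.twinx()
            ax2.plot(self.trace["val_rmse"], color="C1", label="val RMSE (bpm)")
            ax2.set_ylabel("validation RMSE (bpm)")
        ax.legend(loc="upper right")
        return ax

    def save(self, path) -> None:
        """Write the trained network (weights + architecture) to one file."""
        save_model(self.network, path)
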