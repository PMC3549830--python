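"""Model/Results front end for the split–lump MSM pipeline.

``SolventMSM`` is constructed from trajectories plus the modelling choices
(model type, K, σ, lag, annealing budget); ``fit(seed)`` executes
split → count → transition matrix → (optional) lump and returns a
``SolventMSMResults`` carrying the microstate labels, the estimated
transition model, the metastability before and after lumping, the 1/K
random baseline, and the metric-evaluation cost of the split — everything
the model-comparison experiments report.

Three model types exist:

* ``"solute"``   — K microstates by k-center under the Kabsch RMSD metric;
* ``"solvent"``  — K microstates by k-center under the solvent-signature
  metric at bandwidth σ;
* ``"combined"`` — K₁ solute × K₂ solvent product clustering merged down
  to K microstates (defaults K₁ = K₂ = ⌈√K⌉, split cost O((K₁+K₂)·N)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import Clustering, ProductClustering, k_center, product_split
from .lumping import LumpingResult, anneal_lump, lump_labels
from .metrics import SolventSignatureMetric, SoluteRMSDMetric, collect_frames
from .msm import TransitionModel, count_transitions, metastability, transition_matrix
from .signature import KernelParams

__all__ = ["SolventMSM", "SolventMSMResults"]

MODEL_TYPES = ("solute", "solvent", "combined")


class SolventMSM:
    """Markov state model of solvated dynamics, built by split-then-lump.

    Parameters
    ----------
    trajectories : Trajectory or sequence of Trajectory.
    model : "solute", "solvent" or "combined".
    K : number of microstates after the split step.
    K1, K2 : solute/solvent cluster counts for the combined model
        (default ⌈√K⌉ each; must satisfy K₁·K₂ ≥ K).
    L : number of macrostates for the lump step; None skips lumping.
    sigma : Gaussian signature bandwidth, in coordinate units.
    lag_frames : transition-counting lag in frames.
    steps, restarts : simulated-annealing budget for lumping.
    mode : "global" or "nested" solvent clustering for the combined model.
    """

    def __init__(
        self,
        trajectories,
        model: str = "combined",
        K: int = 10,
        K1: int | None = None,
        K2: int | None = None,
        L: int | None = None,
        sigma: float = 1.0,
        lag_frames: int = 1,
        steps: int = 10000,
        restarts: int = 100,
        mode: str = "global",
    ):
        if model not in MODEL_TYPES:
            raise ValueError(f"model must be one of {MODEL_TYPES}")
        if model == "solute" and K2 not in (None, 1):
            raise ValueError("the solute-based model fixes K2 = 1")
        if model == "solvent" and K1 not in (None, 1):
            raise ValueError("the solvent-based model fixes K1 = 1")
        if model == "combined" and K1 is not None and K2 is not None and K1 * K2 < K:
            raise ValueError(f"K1*K2 = {K1 * K2} < K = {K}")
        if hasattr(trajectories, "frames"):
            trajectories = [trajectories]
        self.trajectories = list(trajectories)
        self.frames = collect_frames(self.trajectories)
        if K > len(self.frames):
            raise ValueError("K exceeds the number of frames")
        if L is not None and L > K:
            raise ValueError("L must not exceed K")
        self.model = model
        self.K, self.K1, self.K2, self.L = K, K1, K2, L
        self.sigma = sigma
        self.lag_frames = lag_frames
        self.steps, self.restarts = steps, restarts
        self.mode = mode

    # ------------------------------------------------------------------
    def _label_sequences(self, labels: np.ndarray) -> list[np.ndarray]:
        """Split flat frame labels back into per-trajectory sequences."""
        seqs, start = [], 0
        for t in self.trajectories:
            seqs.append(labels[start: start + len(t)])
            start += len(t)
        return seqs

    def fit(self, seed: int = 0) -> "SolventMSMResults":
        """Run the pipeline and return the fitted results object."""
        solvent_params = KernelParams(sigma=self.sigma, normalized=False)
        if self.model == "solute":
            metric = SoluteRMSDMetric()
            clustering = k_center(self.frames, self.K, metric, seed=seed)
            n_evals = clustering.n_metric_evaluations
        elif self.model == "solvent":
            metric = SolventSignatureMetric(params=solvent_params)
            clustering = k_center(self.frames, self.K, metric, seed=seed)
            n_evals = clustering.n_metric_evaluations
        else:
            clustering = product_split(
                self.frames,
                K=self.K,
                K1=self.K1,
                K2=self.K2,
                solute_metric=SoluteRMSDMetric(),
                solvent_metric=SolventSignatureMetric(params=solvent_params),
                seed=seed,
                mode=self.mode,
            )
            n_evals = clustering.n_metric_evaluations

        labels = clustering.labels
        seqs = self._label_sequences(labels)
        counts = count_transitions(seqs, self.K, lag_frames=self.lag_frames)
        lag_time = self.trajectories[0].lag_time * self.lag_frames
        micro_model = transition_matrix(counts, lag_time=lag_time)
        Q_micro, Qn_micro = metastability(micro_model)

        lump_result = macro_model = None
        macro_labels = None
        if self.L is not None:
            lump_result = anneal_lump(
                counts, self.L, steps=self.steps, restarts=self.restarts, seed=seed
            )
            macro_labels = lump_labels(labels, lump_result.assignment)
            macro_counts = count_transitions(
                self._label_sequences(macro_labels), self.L, self.lag_frames
            )
            macro_model = transition_matrix(macro_counts, lag_time=lag_time)

        return SolventMSMResults(
            model=self,
            seed=seed,
            clustering=clustering,
            labels=labels,
            counts=counts,
            micro_model=micro_model,
            Q_micro=Q_micro,
            Qn_micro=Qn_micro,
            lump_result=lump_result,
            macro_model=macro_model,
            macro_labels=macro_labels,
            n_metric_evaluations=n_evals,
        )


@dataclass
class SolventMSMResults:
    """Fitted split–lump MSM: states, transition model, metastability."""

    model: SolventMSM
    seed: int
    clustering: Clustering | ProductClustering
    labels: np.ndarray
    counts: np.ndarray
    micro_model: TransitionModel
    Q_micro: float
    Qn_micro: float
    lump_result: LumpingResult | None = None
    macro_model: TransitionModel | None = None
    macro_labels: np.ndarray | None = None
    n_metric_evaluations: int = 0

    @property
    def baseline(self) -> float:
        """Expected normalized metastability of random K-state labels, 1/K."""
        return 1.0 / self.model.K

    @property
    def Q_macro(self) -> float | None:
        if self.macro_model is None:
            return None
        return metastability(self.macro_model)[0]

    @property
    def Qn_macro(self) -> float | None:
        if self.macro_model is None:
            return None
        return metastability(self.macro_model)[1]

    # ------------------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Solvent-aware Markov state model",
            "=" * 40,
            f"model type          : {m.model}",
            f"frames (N)          : {len(m.frames)}",
            f"microstates (K)     : {m.K}",
        ]
        if isinstance(self.clustering, ProductClustering):
            lines += [
                f"solute clusters K1  : {self.clustering.solute.K}",
                f"solvent clusters K2 : {self.clustering.solvent.K}",
            ]
        lines += [
            f"sigma               : {m.sigma}",
            f"lag (frames)        : {m.lag_frames}",
            f"metric evaluations  : {self.n_metric_evaluations}",
            f"split Q             : {self.Q_micro:.4f}",
            f"split Q/K           : {self.Qn_micro:.4f}",
            f"random baseline 1/K : {self.baseline:.4f}",
        ]
        if self.lump_result is not None:
            lines += [
                f"macrostates (L)     : {self.lump_result.L}",
                f"lumped Q            : {self.Q_macro:.4f}",
                f"lumped Q/L          : {self.Qn_macro:.4f}",
            ]
        return "\n".join(lines)

    def manifest(self) -> dict:
        """Machine-readable record sufficient to regenerate every output."""
        m = self.model
        out = {
            "model": m.model,
            "K": m.K,
            "K1": m.K1,
            "K2": m.K2,
            "L": m.L,
            "sigma": m.sigma,
            "lag_frames": m.lag_frames,
            "steps": m.steps,
            "restarts": m.restarts,
            "mode": m.mode,
            "seed": self.seed,
            "n_frames": len(m.frames),
            "n_metric_evaluations": int(self.n_metric_evaluations),
            "Q_micro": self.Q_micro,
            "Qn_micro": self.Qn_micro,
            "baseline": self.baseline,
        }
        if isinstance(self.clustering, ProductClustering):
            out["K1_effective"] = self.clustering.solute.K
            out["K2_effective"] = self.clustering.solvent.K
        if self.lump_result is not None:
            out.update(
                Q_macro=self.Q_macro,
                Qn_macro=self.Qn_macro,
                assignment=self.lump_result.assignment.tolist(),
            )
        return out

    def save(self, outdir: str | Path) -> None:
        """Write labels (TSV), the transition model and the manifest (JSON)."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = {"frame_index": np.arange(len(self.labels)), "label": self.labels}
        if self.macro_labels is not None:
            df["macro_label"] = self.macro_labels
        pd.DataFrame(df).to_csv(outdir / "labels.tsv", sep="\t", index=False)
        model_json = {
            "counts": self.counts.tolist(),
            "T": self.micro_model.T.tolist(),
            "lag_time": self.micro_model.lag_time,
            "populations": self.micro_model.populations.tolist(),
        }
        if self.macro_model is not None:
            model_json["macro_T"] = self.macro_model.T.tolist()
            model_json["macro_counts"] = self.macro_model.counts.tolist()
        (outdir / "transition_model.json").write_text(
            json.dumps(model_json, indent=1)
        )
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=1))
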