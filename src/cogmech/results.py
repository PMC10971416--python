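"""Posterior containers and summaries shared by all fitted models."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import rhat

__all__ = ["PosteriorFit", "EffectSummary", "ConvergenceWarning"]

RHAT_THRESHOLD = 1.05


class ConvergenceWarning(UserWarning):
    pass


def _flat_labels(name: str, shape: tuple[int, ...], labels) -> list[str]:
    if not shape:
        return [name]
    if labels is not None:
        return [f"{name}[{lab}]" for lab in labels]
    idx = np.indices(shape).reshape(len(shape), -1).T
    return [name + "[" + ",".join(str(i) for i in ix) + "]" for ix in idx]


@dataclass
class PosteriorFit:
    """MCMC draws plus summaries for a fitted hierarchical model.

    ``draws[name]`` has shape ``(n_chains, n_iter, *param_shape)``. Model
    modules attach whatever metadata downstream analyses need (subject ids,
    arm labels, design arrays) in ``meta``.
    """

    draws: dict[str, np.ndarray]
    n_chains: int
    n_warmup: int
    model: str = ""
    labels: dict[str, list] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    # -- access -----------------------------------------------------------
    @property
    def n_iter(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of a scalar quantity pooled across chains, 1-D."""
        arr = self.draws[name]
        if arr.ndim != 2:
            raise KeyError(f"{name!r} is not scalar; index into .draws")
        return arr.reshape(-1)

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains*n_iter, *shape)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    # -- summaries --------------------------------------------------------
    def summary(self, include_subjects: bool = False) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            if not include_subjects and name in self.meta.get(
                "subject_level", ()
            ):
                continue
            shape = arr.shape[2:]
            flat = arr.reshape(self.n_chains, arr.shape[1], -1)
            labels = _flat_labels(name, shape, self.labels.get(name))
            for k, lab in enumerate(labels):
                x = flat[:, :, k]
                pooled = x.reshape(-1)
                rows.append(
                    {
                        "parameter": lab,
                        "mean": pooled.mean(),
                        "sd": pooled.std(ddof=1),
                        "q05": np.quantile(pooled, 0.05),
                        "q50": np.quantile(pooled, 0.50),
                        "q95": np.quantile(pooled, 0.95),
                        "rhat": rhat(x) if self.n_chains > 1 else np.nan,
                    }
                )
        return pd.DataFrame(rows).set_index("parameter")

    @property
    def max_rhat(self) -> float:
        s = self.summary(include_subjects=True)
        return float(np.nanmax(s["rhat"].values))

    def check_convergence(self, threshold: float = RHAT_THRESHOLD) -> bool:
        """Flag (warn, record, return False) if any R-hat exceeds threshold."""
        mr = self.max_rhat
        ok = bool(mr <= threshold)
        self.info["converged"] = ok
        self.info["max_rhat"] = mr
        if not ok:
            warnings.warn(
                f"fit '{self.model}': max R-hat {mr:.3f} exceeds "
                f"{threshold}; treat posterior summaries with caution",
                ConvergenceWarning,
                stacklevel=2,
            )
        return ok

    # -- persistence ------------------------------------------------------
    def save(self, outdir: str | Path, save_draws: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary(include_subjects=False).to_csv(outdir / "summary.csv")
        if save_draws:
            frames = []
            for name, arr in self.draws.items():
                if name in self.meta.get("subject_level", ()):
                    continue
                flat = arr.reshape(self.n_chains, arr.shape[1], -1)
                labels = _flat_labels(
                    name, arr.shape[2:], self.labels.get(name)
                )
                for k, lab in enumerate(labels):
                    for ch in range(self.n_chains):
                        frames.append(
                            pd.DataFrame(
                                {
                                    "chain": ch,
                                    "iteration": np.arange(arr.shape[1]),
                                    "parameter": lab,
                                    "value": flat[ch, :, k],
                                }
                            )
                        )
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "draws.csv", index=False
            )
        meta = {
            "model": self.model,
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_warmup": self.n_warmup,
            "max_rhat": self.info.get("max_rhat"),
            "converged": self.info.get("converged"),
        }
        (outdir / "fit.json").write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one group-level effect (e.g. an intervention
    shift), with the credible-interval decision rule applied."""

    parameter: str
    mean: float
    ci_low: float
    ci_high: float
    level: float
    excludes_zero: bool
    smd: float | None = None

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "excludes_zero": self.excludes_zero,
            "smd": self.smd,
        }


def effect_from_draws(
    name: str, draws: np.ndarray, level: float = 0.90, smd: float | None = None
) -> EffectSummary:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return EffectSummary(
        parameter=name,
        mean=float(np.mean(draws)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        excludes_zero=bool(lo > 0.0 or hi < 0.0),
        smd=smd,
    )
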