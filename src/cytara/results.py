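"""Shared result container for nonlinear least-squares fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FitResult:
    """Point estimates with Gauss-Newton uncertainty summaries.

    ``covariance`` is the asymptotic sigma^2 (J^T J)^-1 estimate with
    sigma^2 = RSS/(n-p); ``rse`` are relative standard errors in percent.
    ``rmse`` is on the linear observation scale regardless of the fitting
    scale.
    """

    names: tuple[str, ...]
    estimates: np.ndarray
    objective: float
    covariance: np.ndarray | None
    rse: np.ndarray | None
    residuals: np.ndarray
    rmse: float
    n_obs: int
    extra: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def as_dict(self) -> dict:
        out = {
            "estimates": {n: float(v) for n, v in zip(self.names, self.estimates)},
            "objective": float(self.objective),
            "rmse": float(self.rmse),
            "n_obs": int(self.n_obs),
        }
        if self.rse is not None:
            out["rse_percent"] = {n: float(v) for n, v in zip(self.names, self.rse)}
        if self.covariance is not None:
            out["covariance"] = np.asarray(self.covariance).tolist()
        out.update({k: v for k, v in self.extra.items() if np.isscalar(v)})
        return out
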