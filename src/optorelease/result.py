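"""Shared fit-result container with curvature confidence intervals and AIC."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["FitResult", "aic_gaussian", "akaike_weights"]


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """Akaike information criterion for Gaussian residuals.

    ``AIC = n ln(RSS/n) + 2k`` with ``k`` counting the fitted parameters plus
    one for the residual variance.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rss = max(rss, 1e-300)  # guard log of an exactly-zero residual
    return n * float(np.log(rss / n)) + 2 * k


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights exp(-delta/2) normalized over the compared set."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class FitResult:
    """Point estimates, curvature confidence intervals and fit diagnostics.

    ``conf_int`` maps parameter name to a ``(lo, hi)`` 95% interval from the
    local curvature of the residual surface (Gauss-Newton approximation).
    ``flags`` collects non-fatal diagnostics, e.g. unidentifiable parameters
    or active bounds; ``converged`` is False only when the optimizer itself
    failed.
    """

    variant: str
    params: dict[str, float]
    stderr: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    rss: float
    n_obs: int
    aic: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    akaike_weight: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def ci_width(self, name: str) -> float:
        lo, hi = self.conf_int[name]
        return hi - lo

    @classmethod
    def from_least_squares(
        cls,
        res,
        names: list[str],
        variant: str = "",
        n_obs: int | None = None,
        extra: dict[str, Any] | None = None,
    ) -> "FitResult":
        """Build a result from a ``scipy.optimize.least_squares`` solution."""
        resid = np.asarray(res.fun, dtype=float)
        n = n_obs if n_obs is not None else resid.size
        rss = float(resid @ resid)
        p = len(names)
        flags: list[str] = []

        J = np.asarray(res.jac, dtype=float)
        col_norms = np.linalg.norm(J, axis=0)
        dead = col_norms <= 1e-12 * max(1.0, np.linalg.norm(J))
        stderr: dict[str, float] = {}
        cis: dict[str, tuple[float, float]] = {}
        dof = max(n - p, 1)
        sigma2 = rss / dof
        JtJ = J.T @ J
        # pseudo-inverse tolerates unidentifiable directions; those get
        # infinite intervals and an explicit flag
        cov = sigma2 * np.linalg.pinv(JtJ)
        for i, name in enumerate(names):
            if dead[i]:
                flags.append(f"unidentifiable: {name}")
                stderr[name] = np.inf
                cis[name] = (-np.inf, np.inf)
                continue
            se = float(np.sqrt(max(cov[i, i], 0.0)))
            stderr[name] = se
            est = float(res.x[i])
            cis[name] = (est - 1.96 * se, est + 1.96 * se)
        if hasattr(res, "active_mask") and np.any(res.active_mask != 0):
            for i, name in enumerate(names):
                if res.active_mask[i] != 0:
                    flags.append(f"active bound: {name}")

        return cls(
            variant=variant,
            params={name: float(v) for name, v in zip(names, res.x)},
            stderr=stderr,
            conf_int=cis,
            rss=rss,
            n_obs=n,
            aic=aic_gaussian(rss, n, p + 1),
            converged=bool(res.success),
            flags=flags,
            extra=extra or {},
        )

    def to_json(self) -> str:
        def clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return None if np.isnan(v) else ("inf" if v > 0 else "-inf")
            return v

        payload = {
            "variant": self.variant,
            "params": {k: clean(v) for k, v in self.params.items()},
            "stderr": {k: clean(v) for k, v in self.stderr.items()},
            "conf_int": {
                k: [clean(v[0]), clean(v[1])] for k, v in self.conf_int.items()
            },
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "akaike_weight": self.akaike_weight,
            "converged": self.converged,
            "flags": self.flags,
        }
        return json.dumps(payload, indent=2)
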