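"""Residual-bootstrap uncertainty for one-tissue-compartment fits.

Replicate curves are formed by adding resampled *weighted* residuals back
onto the fitted curve (rescaled by the destination frame's weight so the
error structure the objective assumes is preserved), and each replicate is
refitted with the original fit settings.  The standard deviation across
replicates estimates the parameter uncertainty plotted as error bars on
longitudinal K1/VT trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .input_function import InputFunction
from .kinetics import KineticFit, fit_1tcm
from .tac_core import TimeActivityCurve

_PARAM_COLS = ["k1", "k2", "va", "vt"]


@dataclass(frozen=True)
class BootstrapResult:
    """Per-replicate parameter draws plus bookkeeping.

    ``replicates`` holds one row per *successful* refit (columns k1, k2, va,
    vt, with vt = k1/k2 of that same replicate); failures are dropped and
    counted in ``n_failed``.
    """

    replicates: pd.DataFrame
    n_requested: int
    n_failed: int
    seed: int

    def __post_init__(self):
        if self.n_requested < 1:
            raise ValidationError("n_replicates must be >= 1")
        if list(self.replicates.columns) != _PARAM_COLS:
            raise ValidationError(f"replicates must have columns {_PARAM_COLS}")

    @property
    def n_success(self) -> int:
        return len(self.replicates)

    def sd(self) -> pd.Series:
        """Sample standard deviation (ddof=1) per parameter over successes."""
        return self.replicates.std(ddof=1)

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)


def residual_bootstrap(
    fit: KineticFit, aif: InputFunction, n: int = 200, seed: int = 0
) -> BootstrapResult:
    """Residual bootstrap around a converged fit.

    For each replicate, weighted residuals ``e_i = sqrt(w_i) r_i`` (inflated
    by ``sqrt(n/(n-p))`` to undo the downward bias of fitted residuals) are
    resampled with replacement and placed back as ``e_pi(i) / sqrt(w_i)`` on
    the fitted curve; the replicate TAC is refitted with the fit's own
    weighting, Va formulation and multi-start settings.  Deterministic for a
    fixed seed.
    """
    if not fit.converged:
        raise ValidationError("residual bootstrap requires a converged fit")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sw = np.sqrt(fit.weights)
    nf = fit.residuals.size
    # fitted residuals understate the error scale because p parameters were
    # estimated from n frames; inflate by sqrt(n / (n - p)), the standard
    # variance correction for regression residual bootstraps
    n_params = 3
    inflate = np.sqrt(nf / max(nf - n_params, 1))
    e = inflate * sw * fit.residuals
    rows = []
    n_failed = 0
    for _ in range(n):
        idx = rng.integers(0, nf, nf)
        values = fit.fitted + e[idx] / sw
        tac = TimeActivityCurve(
            values, schedule=fit.schedule, decay_corrected=True, decay_reference_min=0.0
        )
        refit = fit_1tcm(
            tac,
            aif,
            weights=fit.weights,
            va_formulation=fit.va_formulation,
            hold_last=fit.hold_last,
        )
        if refit.converged:
            p = refit.params
            rows.append((p.k1, p.k2, p.va, refit.vt))
        else:
            n_failed += 1
    replicates = pd.DataFrame(rows, columns=_PARAM_COLS)
    return BootstrapResult(replicates=replicates, n_requested=n, n_failed=n_failed, seed=seed)


def summarize_uncertainty(result: BootstrapResult) -> pd.DataFrame:
    """Mean, SD and 2.5/97.5 percentiles per parameter and for VT."""
    if result.n_success == 0:
        raise ValidationError("all bootstrap replicates failed; nothing to summarise")
    if result.n_success < 2:
        raise ValidationError("need >= 2 successful replicates for an SD")
    rep = result.replicates
    return pd.DataFrame(
        {
            "mean": rep.mean(),
            "sd": rep.std(ddof=1),
            "p2.5": rep.quantile(0.025),
            "p97.5": rep.quantile(0.975),
        }
    )
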