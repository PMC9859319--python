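"""Stochastic hill-climbing search over the LS-SVM hyperparameters.

The tuning objective is the mean squared residual

    G(sigma, gamma) = (1/m) sum_j [y_j - y(x_j; sigma, gamma)]^2

evaluated either on the training points themselves (``train`` mode, the
literal objective), on a chronological holdout block (``holdout``), or by
leave-one-out cross-validation (``loocv``).  The search starts from a point
(sigma0, gamma0), proposes additive random steps, accepts a proposal
whenever it does not increase G, and stops when G falls to the tolerance
``epsilon`` or the iteration cap is reached.

Two step modes are provided.  ``one_sided`` draws both steps from
U(0, 1); strictly positive steps can only ever increase sigma and gamma,
a one-directional drift kept as the procedure was originally formulated.
``symmetric`` (the practical default) draws signed steps from
U(-delta, +delta) per coordinate and rejects proposals that leave the
positive orthant, which lets the walk explore in every direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecohealth.lssvm import KernelParams, LSSVMValidationError, fit, loo_residuals, predict


class SearchConfigError(ValueError):
    """Raised when a search configuration violates its invariants."""


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the stochastic (sigma, gamma) search.

    ``step_scale`` sets the half-width (delta_sigma, delta_gamma) of the
    symmetric-mode proposal distribution; it is ignored in one_sided mode,
    whose steps are always U(0, 1).  The default gamma half-width is much
    larger than sigma's because on standardized predictors useful sigma
    values sit within an O(1) range while the objective is flat in gamma
    over hundreds of units — additive steps must be able to cross that
    plateau within the iteration budget.
    """

    init_sigma: float = 1.0
    init_gamma: float = 10.0
    epsilon: float = 0.0
    max_iter: int = 300
    seed: int = 0
    step_mode: str = "symmetric"
    objective_mode: str = "train"
    step_scale: tuple[float, float] = (0.5, 50.0)
    holdout_size: int = 3

    def __post_init__(self) -> None:
        if self.init_sigma <= 0 or self.init_gamma <= 0:
            raise SearchConfigError("initial point must be strictly positive")
        if self.epsilon < 0:
            raise SearchConfigError("epsilon must be >= 0")
        if self.max_iter < 1:
            raise SearchConfigError("max_iter must be >= 1")
        if self.step_mode not in ("one_sided", "symmetric"):
            raise SearchConfigError(f"unknown step_mode {self.step_mode!r}")
        if self.objective_mode not in ("train", "holdout", "loocv"):
            raise SearchConfigError(f"unknown objective_mode {self.objective_mode!r}")
        if min(self.step_scale) <= 0:
            raise SearchConfigError("step_scale entries must be positive")
        if self.holdout_size < 1:
            raise SearchConfigError("holdout_size must be >= 1")


@dataclass
class SearchTrace:
    """Per-iteration record of the search and its final state.

    ``iterations`` rows are (iteration, sigma, gamma, G, accepted) for every
    *proposal*; the sequence of G values over accepted proposals is
    non-increasing by construction.
    """

    iterations: list[tuple[int, float, float, float, bool]] = field(default_factory=list)
    final_params: KernelParams | None = None
    final_G: float = np.inf
    stop_reason: str = ""
    n_accepted: int = 0

    @property
    def accepted_G(self) -> list[float]:
        return [g for (_, _, _, g, acc) in self.iterations if acc]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.iterations, columns=["iteration", "sigma", "gamma", "G", "accepted"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def objective_G(
    inputs,
    targets,
    params: KernelParams,
    objective_mode: str = "train",
    holdout_size: int = 3,
) -> float:
    """Mean squared residual of the LS-SVM at the given hyperparameters.

    ``train`` fits on all samples and scores the fit on those same samples;
    ``holdout`` fits on all but the last ``holdout_size`` samples (the input
    order is taken as chronological) and scores the held-out block;
    ``loocv`` averages the squared leave-one-out prediction errors.
    """
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if objective_mode == "train":
        model = fit(X, y, params)
        resid = y - predict(model, X)
        return float(np.mean(resid**2))
    if n < 3:
        raise LSSVMValidationError(f"{objective_mode} objective needs >= 3 samples")
    if objective_mode == "holdout":
        k = min(holdout_size, n - 2)
        model = fit(X[:-k], y[:-k], params)
        resid = y[-k:] - predict(model, X[-k:])
        return float(np.mean(resid**2))
    if objective_mode == "loocv":
        errs = loo_residuals(X, y, params)
        return float(np.mean(errs**2))
    raise SearchConfigError(f"unknown objective_mode {objective_mode!r}")


def search(inputs, targets, config: SearchConfig) -> SearchTrace:
    """Run the stochastic hyperparameter search.

    The returned trace satisfies G(final) <= G(init) and is fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    trace = SearchTrace()

    sigma, gamma = config.init_sigma, config.init_gamma
    G_curr = objective_G(
        inputs, targets, KernelParams(sigma, gamma),
        config.objective_mode, config.holdout_size,
    )

    stop_reason = "max_iter"
    for k in range(1, config.max_iter + 1):
        if G_curr <= config.epsilon:
            stop_reason = "tolerance"
            break
        if config.step_mode == "one_sided":
            step_s, step_g = rng.uniform(0.0, 1.0, size=2)
        else:
            ds, dg = config.step_scale
            step_s = rng.uniform(-ds, ds)
            step_g = rng.uniform(-dg, dg)
        cand_s, cand_g = sigma + step_s, gamma + step_g
        if cand_s <= 0 or cand_g <= 0:  # cannot occur in one_sided mode
            trace.iterations.append((k, cand_s, cand_g, np.inf, False))
            continue
        G_cand = objective_G(
            inputs, targets, KernelParams(cand_s, cand_g),
            config.objective_mode, config.holdout_size,
        )
        accepted = G_cand <= G_curr
        trace.iterations.append((k, cand_s, cand_g, G_cand, accepted))
        if accepted:
            sigma, gamma, G_curr = cand_s, cand_g, G_cand
            trace.n_accepted += 1
    else:
        stop_reason = "max_iter"
    if G_curr <= config.epsilon:
        stop_reason = "tolerance"

    trace.final_params = KernelParams(sigma, gamma)
    trace.final_G = G_curr
    trace.stop_reason = stop_reason
    return trace
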