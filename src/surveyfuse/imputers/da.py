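"""Data augmentation: joint latent-normal imputation with parameter draws.

The common and specific blocks are embedded in one multivariate normal
vector (categorical variables entering through reference-dropped indicator
columns).  The chain alternates

* an **I-step** — draw the missing specific features of every recipient from
  their conditional normal distribution given the observed common features
  and the current parameters, and
* a **P-step** — draw (mean, covariance) from their posterior (normal —
  inverse-Wishart under the Jeffreys prior) given the current completed
  data,

so retained imputations reflect both residual and parameter uncertainty.
Categorical specific values are decoded from the drawn latent indicators by
a stochastic draw over the implied level scores, keeping the imputation a
simulation of instances rather than a conditional-mode rule.  Draws
retained after burn-in at a fixed spacing are (near-)independent completed
tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..design import indicator_matrix
from ..schema import FusionSpec, SurveyDataError, SurveyTable, check_schema_set


class DataAugmentation:
    """Model object for joint latent-normal data augmentation."""

    method = "data_augmentation"

    def __init__(self, donor: SurveyTable, spec: FusionSpec, ridge: float = 1e-8):
        spec.validate_against(donor.schema)
        if not donor.is_complete(spec.specific_names):
            raise SurveyDataError("donor file has missing specific values")
        self.donor = donor
        self.spec = spec
        self.ridge = float(ridge)
        self.schema_map = check_schema_set(donor.schema)

    def fit(self) -> "DataAugmentationResults":
        X, xnames = indicator_matrix(
            self.donor.df, list(self.spec.common_names), self.schema_map
        )
        Y, ynames = indicator_matrix(
            self.donor.df, list(self.spec.specific_names), self.schema_map
        )
        W = np.hstack([X, Y])
        cov = np.cov(W, rowvar=False)
        if np.linalg.matrix_rank(cov[X.shape[1]:, X.shape[1]:]) < Y.shape[1]:
            raise SurveyDataError(
                "degenerate covariance of the specific block on donors"
            )
        return DataAugmentationResults(self, xnames, ynames, W, X.shape[1])


class DataAugmentationResults:
    """Fitted feature embedding; :meth:`impute` runs the DA chain."""

    method = "data_augmentation"

    def __init__(self, model, xnames, ynames, donor_features, n_x):
        self.model = model
        self.xnames = xnames
        self.ynames = ynames
        self._donor_features = donor_features
        self._n_x = n_x

    def _safe_cholesky(self, mat: np.ndarray) -> np.ndarray:
        ridge = max(self.model.ridge, 1e-12) * max(np.trace(mat) / len(mat), 1.0)
        for _ in range(12):
            try:
                return np.linalg.cholesky(mat + ridge * np.eye(len(mat)))
            except np.linalg.LinAlgError:
                ridge *= 10.0
        raise np.linalg.LinAlgError("scatter matrix not positive definite")

    def _decode(
        self, recipient: SurveyTable, Y: np.ndarray, rng: np.random.Generator
    ) -> SurveyTable:
        """Map drawn latent features back to survey values.

        Categorical specifics are decoded *stochastically*: the drawn
        indicator scores are clipped to [0, 1], normalised, and a level is
        drawn from them.  (Rounding to the most probable level would be a
        conditional-mode imputation, which the stochastic-simulation
        objective rules out.)
        """
        out = recipient.df.copy()
        pos = 0
        for name in self.model.spec.specific_names:
            var = self.model.schema_map[name]
            if var.is_categorical:
                k = len(var.levels) - 1
                block = Y[:, pos:pos + k]
                scores = np.column_stack([1.0 - block.sum(axis=1), block])
                probs = np.clip(scores, 0.0, 1.0) + 1e-12
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random(len(probs))[:, None]
                idx = (u > np.cumsum(probs, axis=1)).sum(axis=1)
                out[name] = np.asarray(var.levels, dtype=object)[idx]
                pos += k
            else:
                out[name] = Y[:, pos]
                pos += 1
        return SurveyTable(out, recipient.schema, check=False)

    def impute(
        self,
        recipient: SurveyTable,
        burn_in: int = 500,
        n_draws: int = 1,
        spacing: int = 100,
        seed: int = 0,
    ) -> list[SurveyTable]:
        """Run the I/P chain and return ``n_draws`` completed tables."""
        if burn_in < 1 or n_draws < 1 or spacing < 1:
            raise ValueError("burn_in, n_draws and spacing must all be >= 1")
        if recipient.n == 0:
            raise SurveyDataError("recipient table is empty")
        rng = np.random.default_rng(seed)
        m = self.model
        nx = self._n_x
        Xr, _ = indicator_matrix(
            recipient.df, list(m.spec.common_names), m.schema_map
        )
        W0 = self._donor_features
        d = W0.shape[1]
        ny = d - nx

        mu = W0.mean(axis=0)
        sigma = np.cov(W0, rowvar=False) + self.model.ridge * np.eye(d)

        completed: list[SurveyTable] = []
        total_iters = burn_in + (n_draws - 1) * spacing + 1
        Yr = np.empty((len(Xr), ny))
        for it in range(total_iters):
            # I-step: recipients' specific features | common features, theta
            Sxx = sigma[:nx, :nx]
            Sxy = sigma[:nx, nx:]
            Syy = sigma[nx:, nx:]
            A = np.linalg.solve(Sxx + self.model.ridge * np.eye(nx), Sxy).T
            mean_y = mu[nx:] + (Xr - mu[:nx]) @ A.T
            cond = Syy - A @ Sxy
            cond = (cond + cond.T) / 2.0
            L = self._safe_cholesky(cond)
            Yr = mean_y + rng.standard_normal((len(Xr), ny)) @ L.T

            # P-step: theta | completed data (Jeffreys prior)
            W = np.vstack([W0, np.hstack([Xr, Yr])])
            n = len(W)
            wbar = W.mean(axis=0)
            S = (W - wbar).T @ (W - wbar)
            df = max(n - 1, d + 2)
            try:
                sigma = stats.invwishart.rvs(df=df, scale=S, random_state=rng)
            except np.linalg.LinAlgError:
                sigma = S / n + 10 * self.model.ridge * np.eye(d)
            sigma = (sigma + sigma.T) / 2.0
            mu = wbar + self._safe_cholesky(sigma / n) @ rng.standard_normal(d)

            if it >= burn_in and (it - burn_in) % spacing == 0:
                completed.append(self._decode(recipient, Yr, rng))
                if len(completed) == n_draws:
                    break
        return completed


def da_impute(
    donor: SurveyTable,
    recipient: SurveyTable,
    spec: FusionSpec,
    burn_in: int = 500,
    n_draws: int = 1,
    spacing: int = 100,
    seed: int = 0,
) -> list[SurveyTable]:
    """One-call convenience wrapper around :class:`DataAugmentation`."""
    return DataAugmentation(donor, spec).fit().impute(
        recipient, burn_in=burn_in, n_draws=n_draws, spacing=spacing, seed=seed
    )
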