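"""Model-based stability via intra-/inter-group variance decomposition.

The model treats each Ct value as candidate baseline + shared per-sample
loading + group-specific deviation + candidate noise.  Centering every
sample by its across-candidate mean removes the shared loading exactly;
what remains per candidate splits into an intragroup variance and an
intergroup deviation, and the stability value combines both (lower = more
stable).

Estimator details
-----------------
Let k be the candidate count, G the group count and n_g the group sizes.
With Ct values y_igj (candidate i, group g, sample j):

1. center each candidate by its grand mean;
2. within each sample subtract the across-candidate mean, giving x_igj;
3. intergroup deviation d_ig = mean_j x_igj  (sums to 0 over i within g);
4. observed centered variance s2_ig = Var_j(x_igj), n_g - 1 denominator;
5. the across-candidate centering biases s2; the method-of-moments
   inversion of Var(x_i) = ((k-1)^2/k^2) s2_i + (1/k^2) sum_{i'!=i} s2_{i'}
   gives the corrected intragroup variance
   sigma2_ig = max(0, (k/(k-2)) * (s2_ig - S_g / (k (k-1)))),  S_g = sum_i s2_ig;
6. the between-candidate variance of group deviations is estimated as
   gamma2 = max(0, Var_{i,g}(d_ig) - mean_{i,g}(sigma2_ig / n_g));
7. deviations are shrunk toward zero, d~_ig = d_ig * gamma2 / (gamma2 + sigma2_ig/n_g),
   which keeps the stability finite and stable when gamma2 is tiny.

Stability: rho_i = (1/G) * sum_g ( |d~_ig| + sqrt(sigma2_ig / n_g) ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_io import CtTable
from .errors import ContractError


@dataclass
class NormFinderDecomposition:
    candidates: list[str]
    groups: list[str]
    n_g: np.ndarray            # per-group sample sizes, shape (G,)
    s2: np.ndarray             # observed centered variance, shape (k, G)
    sigma2: np.ndarray         # corrected intragroup variance, shape (k, G)
    d_hat: np.ndarray          # intergroup deviation, shape (k, G)
    d_tilde: np.ndarray        # shrunken deviation, shape (k, G)
    gamma2_d: float            # between-candidate variance of deviations

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.groups):
            for ci, c in enumerate(self.candidates):
                rows.append(
                    {
                        "candidate": c,
                        "group": g,
                        "s2": self.s2[ci, gi],
                        "sigma2": self.sigma2[ci, gi],
                        "d_hat": self.d_hat[ci, gi],
                        "d_tilde": self.d_tilde[ci, gi],
                    }
                )
        return pd.DataFrame(rows)


def _centered_residuals(ct: np.ndarray) -> np.ndarray:
    """Remove candidate grand means, then per-sample across-candidate means."""
    z = ct - ct.mean(axis=1, keepdims=True)
    return z - z.mean(axis=0, keepdims=True)


def _corrected_sigma2(s2_per_candidate: np.ndarray, k: int) -> np.ndarray:
    total = s2_per_candidate.sum()
    return np.maximum(0.0, (k / (k - 2)) * (s2_per_candidate - total / (k * (k - 1))))


def normfinder_decompose(table: CtTable) -> NormFinderDecomposition:
    """Full intra-/inter-group decomposition (requires k >= 3 and >= 2 groups)."""
    k = table.n_candidates
    if k < 3:
        raise ContractError("decomposition needs >= 3 candidates (k/(k-2) correction)")
    groups = table.groups
    if len(groups) < 2:
        raise ContractError(
            "single group supplied; use normfinder_singlegroup for the group-free variant"
        )
    table.require_groups()
    G = len(groups)
    x = _centered_residuals(table.ct)
    n_g = np.empty(G, dtype=int)
    s2 = np.empty((k, G))
    sigma2 = np.empty((k, G))
    d_hat = np.empty((k, G))
    for gi, g in enumerate(groups):
        cols = table.group_columns(g)
        n_g[gi] = len(cols)
        block = x[:, cols]
        d_hat[:, gi] = block.mean(axis=1)
        s2[:, gi] = block.var(axis=1, ddof=1)
        sigma2[:, gi] = _corrected_sigma2(s2[:, gi], k)
    gamma2 = max(0.0, float(np.var(d_hat, ddof=1)) - float(np.mean(sigma2 / n_g)))
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(
            gamma2 + sigma2 / n_g > 0, gamma2 / (gamma2 + sigma2 / n_g), 0.0
        )
    d_tilde = d_hat * shrink
    return NormFinderDecomposition(
        candidates=list(table.candidates),
        groups=list(groups),
        n_g=n_g,
        s2=s2,
        sigma2=sigma2,
        d_hat=d_hat,
        d_tilde=d_tilde,
        gamma2_d=gamma2,
    )


def normfinder_stability(decomp: NormFinderDecomposition) -> pd.Series:
    """Stability rho_i = mean over groups of |d~_ig| + sqrt(sigma2_ig/n_g)."""
    per_group = np.abs(decomp.d_tilde) + np.sqrt(decomp.sigma2 / decomp.n_g)
    rho = per_group.mean(axis=1)
    return pd.Series(rho, index=decomp.candidates, name="stability")


def normfinder(table: CtTable) -> pd.Series:
    """Convenience: decomposition + stability in one call."""
    return normfinder_stability(normfinder_decompose(table))


def normfinder_singlegroup(table: CtTable) -> pd.Series:
    """Group-free variant: rho_i = sqrt(corrected sigma2_i) on the pooled samples."""
    k = table.n_candidates
    if k < 3:
        raise ContractError("needs >= 3 candidates (k/(k-2) correction)")
    x = _centered_residuals(table.ct)
    s2 = x.var(axis=1, ddof=1)
    sigma2 = _corrected_sigma2(s2, k)
    return pd.Series(np.sqrt(sigma2), index=table.candidates, name="stability")
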