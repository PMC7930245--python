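"""True presence of a variant vs sequencing noise, per site and sample.

Each somatic site gets its own beta-binomial error model: alt reads in
samples that do not carry the variant are treated as miscalls with
site-specific rate mu and overdispersion rho (the usual (mu, rho)
parameterisation, alpha = mu(1-rho)/rho, beta = (1-mu)(1-rho)/rho). The
model is fitted by maximum likelihood over a 25-point logarithmic grid for
rho with a closed-form weighted-mean profile for mu at each grid point,
using only samples whose naive VAF is below a contamination threshold.

A sample is called as truly carrying the variant when the upper-tail
probability P(X >= alt) under the fitted noise model falls below the
presence threshold (default 1e-3, no multiplicity correction).

At the lowest grid point the model is evaluated as its exact rho -> 0
limit, a plain binomial; this keeps the floor numerically exact instead of
pushing huge shape parameters through the beta-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import VariantTable

RHO_MIN = 1e-6
RHO_MAX = 0.89
N_RHO_GRID = 25
MU_MIN = 1e-6
MU_MAX = 0.499

DEFAULT_THRESHOLD = 1e-3
DEFAULT_VAF_FIT_MAX = 0.1


class ErrorFitError(ValueError):
    """Raised when a site-specific error model cannot be fitted."""


def rho_grid(n: int = N_RHO_GRID) -> np.ndarray:
    return np.logspace(np.log10(RHO_MIN), np.log10(RHO_MAX), n)


@dataclass(frozen=True)
class SiteErrorModel:
    """Fitted site-specific sequencing-noise model."""

    mu: float
    rho: float
    n_samples_used: int
    pooled: bool = False

    def __post_init__(self):
        if not MU_MIN <= self.mu <= MU_MAX:
            raise ValueError("mu outside (0, 0.5)")
        if not RHO_MIN <= self.rho <= RHO_MAX:
            raise ValueError("rho outside grid bounds")


@dataclass
class PresenceCall:
    """Per site x sample presence decisions with supporting p-values."""

    p_values: pd.DataFrame
    present: pd.DataFrame
    threshold: float
    models: pd.DataFrame  # per-site mu, rho, n_samples_used, pooled
    alt: pd.DataFrame
    depth: pd.DataFrame

    @property
    def degenerate(self) -> pd.DataFrame:
        """Cells with zero depth (p fixed at 1)."""
        return self.depth == 0


def _betabinom_ab(mu, rho):
    scale = (1.0 - rho) / rho
    return mu * scale, (1.0 - mu) * scale


def _noise_logpmf(alt, depth, mu, rho):
    """Log pmf under the noise model; exact binomial limit at the rho floor."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    mu_b = np.broadcast_to(np.asarray(mu, dtype=float), alt.shape)
    rho_b = np.broadcast_to(np.asarray(rho, dtype=float), alt.shape)
    a, b = _betabinom_ab(mu_b, np.maximum(rho_b, RHO_MIN))
    out = stats.betabinom.logpmf(alt, depth, a, b)
    floor = rho_b <= RHO_MIN
    if np.any(floor):
        binom = stats.binom.logpmf(alt, depth, mu_b)
        out = np.where(floor, binom, out)
    return out


def _noise_sf(alt, depth, mu, rho):
    """Upper tail P(X >= alt); exact binomial limit at the rho floor."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    mu_b = np.broadcast_to(np.asarray(mu, dtype=float), alt.shape)
    rho_b = np.broadcast_to(np.asarray(rho, dtype=float), alt.shape)
    a, b = _betabinom_ab(mu_b, np.maximum(rho_b, RHO_MIN))
    out = stats.betabinom.sf(alt - 1, depth, a, b)
    floor = rho_b <= RHO_MIN
    if np.any(floor):
        binom = stats.binom.sf(alt - 1, depth, mu_b)
        out = np.where(floor, binom, out)
    return np.where(alt <= 0, 1.0, np.where(depth <= 0, 1.0, out))


#: log-likelihood gain required for rho to leave the binomial floor;
#: 2.0 corresponds to a boundary likelihood-ratio test at roughly the 2-3%
#: level for the single extra parameter and stops one stray read pair from
#: inflating the tail of a fit on a handful of samples
RHO_PENALTY = 2.0


def _grid_fit(alt: np.ndarray, depth: np.ndarray, mask: np.ndarray, mu_floor=MU_MIN):
    """Vectorised grid ML fit for many sites at once.

    ``alt``/``depth``/``mask`` are (n_sites, n_samples); masked-out cells do
    not contribute. ``mu_floor`` (scalar or per-site) bounds the rate from
    below inside the profile, so the floor participates in rho selection.
    Returns (mu, rho, n_used) arrays of length n_sites.

    Small-sample guards on the overdispersion: rho stays at the binomial
    floor unless (a) at least two masked-in samples carry variant reads —
    with fewer, across-sample rate variability is not identifiable and the
    fit drifts along the degenerate (mu -> 0, rho -> max) ridge — and
    (b) the best rho improves the log likelihood by :data:`RHO_PENALTY`.
    Ties resolve to the smallest rho (argmax is first-hit).
    """
    grid = rho_grid()
    n_sites = alt.shape[0]
    floor = np.broadcast_to(np.asarray(mu_floor, dtype=float), (n_sites,))
    mus = np.empty((grid.size, n_sites))
    logliks = np.full((grid.size, n_sites), -np.inf)
    d = np.where(mask, depth, 0).astype(float)
    a = np.where(mask, alt, 0).astype(float)
    for i, rho in enumerate(grid):
        w = 1.0 / (1.0 + (d - 1.0) * rho)  # per-read weight; mu profile
        num = (a * w).sum(axis=1)
        den = (d * w).sum(axis=1)
        mu = np.clip(
            np.divide(num, den, out=np.zeros(n_sites), where=den > 0), floor, MU_MAX
        )
        mus[i] = mu
        lp = _noise_logpmf(alt, depth, mu[:, None], rho)
        logliks[i] = np.where(mask, lp, 0.0).sum(axis=1)
    best = np.argmax(logliks, axis=0)
    idx = np.arange(n_sites)
    gain = logliks[best, idx] - logliks[0, idx]
    identifiable = ((a > 0) & mask).sum(axis=1) >= 2
    best = np.where(identifiable & (gain >= RHO_PENALTY), best, 0)
    mu_best, rho_best = mus[best, idx], grid[best]
    no_alt = a.sum(axis=1) == 0
    mu_best = np.where(no_alt, floor, mu_best)
    rho_best = np.where(no_alt, RHO_MIN, rho_best)
    return mu_best, rho_best, mask.sum(axis=1)


def fit_site_error(alt_counts, depths) -> SiteErrorModel:
    """Fit the noise model for one site from non-carrier samples.

    Requires at least two samples with depth >= 1.
    """
    alt = np.asarray(alt_counts, dtype=int)
    depth = np.asarray(depths, dtype=int)
    if alt.shape != depth.shape or alt.ndim != 1:
        raise ValueError("alt_counts and depths must be equal-length vectors")
    usable = depth >= 1
    if usable.sum() < 2:
        raise ErrorFitError("need at least two samples with non-zero depth")
    mu, rho, n_used = _grid_fit(alt[None, :], depth[None, :], usable[None, :])
    return SiteErrorModel(mu=float(mu[0]), rho=float(rho[0]), n_samples_used=int(n_used[0]))


def presence_pvalue(alt: int, depth: int, model: SiteErrorModel) -> float:
    """Upper-tail P(X >= alt) under the site's noise model; 1 when alt = 0."""
    if alt > depth:
        raise ValueError("alt exceeds depth")
    return float(_noise_sf(np.array([alt]), np.array([depth]), model.mu, model.rho)[0])


def call_presence(
    table: VariantTable,
    threshold: float = DEFAULT_THRESHOLD,
    vaf_fit_max: float = DEFAULT_VAF_FIT_MAX,
) -> PresenceCall:
    """Call true presence of each (somatic) site in each sample.

    Per site the error model is fitted on samples with naive VAF below
    ``vaf_fit_max`` (candidate non-carriers), leave-one-out: the tested
    sample's own reads never enter the model it is tested against, so a
    borderline carrier cannot mask itself. When fewer than two low-VAF
    samples remain for a test, that test falls back to a pooled error
    model fitted across all low-VAF cells of the table (sites touched by
    the fallback are flagged ``pooled`` in the output).
    """
    alt = table.alt.to_numpy()
    depth = table.depth.to_numpy()
    n_sites, n_samples = alt.shape
    vaf = np.divide(alt, depth, out=np.zeros_like(alt, dtype=float), where=depth > 0)
    fit_mask = (vaf < vaf_fit_max) & (depth >= 1)

    # pooled fallback model over every low-VAF cell of the table
    cells = fit_mask.ravel()
    if cells.sum() < 2:  # pathological table: pool over every covered cell
        cells = (depth >= 1).ravel()
    if cells.sum() < 2:
        raise ErrorFitError("cannot fit a pooled error model: no covered cells")
    pooled_mu, pooled_rho, _ = _grid_fit(
        alt.ravel()[None, cells], depth.ravel()[None, cells], np.ones((1, cells.sum()), bool)
    )
    pooled_mu, pooled_rho = float(pooled_mu[0]), float(pooled_rho[0])

    # Leave-one-out: sample s is tested against the model fitted on the
    # *other* low-VAF samples, so a borderline carrier cannot deflate its
    # own evidence. mu is floored at the fit's measurement resolution
    # (half a read over the summed depth).
    p = np.ones((n_sites, n_samples))
    pooled_used = np.zeros(n_sites, dtype=bool)
    for j in range(n_samples):
        mask_j = fit_mask.copy()
        mask_j[:, j] = False
        n_j = mask_j.sum(axis=1)
        ok = n_j >= 2
        mu_col = np.full(n_sites, pooled_mu)
        rho_col = np.full(n_sites, pooled_rho)
        if ok.any():
            d_tot = np.where(mask_j[ok], depth[ok], 0).sum(axis=1)
            m, r, _ = _grid_fit(
                alt[ok], depth[ok], mask_j[ok], mu_floor=0.5 / np.maximum(d_tot, 1)
            )
            mu_col[ok] = m
            rho_col[ok] = r
        pooled_used |= ~ok
        p[:, j] = _noise_sf(alt[:, j], depth[:, j], mu_col, rho_col)

    # per-site summary model on the full low-VAF sample set (for reporting)
    n_low = fit_mask.sum(axis=1)
    mu = np.full(n_sites, pooled_mu)
    rho = np.full(n_sites, pooled_rho)
    ok_site = n_low >= 2
    if ok_site.any():
        mu[ok_site], rho[ok_site], _ = _grid_fit(alt[ok_site], depth[ok_site], fit_mask[ok_site])
    pooled_used |= ~ok_site

    p_df = pd.DataFrame(p, index=table.site_ids, columns=table.samples)
    present = (p_df < threshold) & (table.alt > 0) & (table.depth > 0)
    models = pd.DataFrame(
        {"mu": mu, "rho": rho, "n_samples_used": n_low, "pooled": pooled_used},
        index=table.site_ids,
    )
    return PresenceCall(
        p_values=p_df,
        present=present,
        threshold=threshold,
        models=models,
        alt=table.alt.copy(),
        depth=table.depth.copy(),
    )


def shared_mutation_counts(call: PresenceCall) -> pd.DataFrame:
    """Sites jointly present in each sample pair (diagonal: per-sample totals).

    This is the statistic behind 'mutations shared between two tissues':
    somatic sites whose presence test fires in both members of the pair.
    """
    z = call.present.to_numpy().astype(int)
    shared = z.T @ z
    return pd.DataFrame(shared, index=call.present.columns, columns=call.present.columns)
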