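"""Germline/somatic classification and depth-based site filters.

Germline and somatic variants are distinguished with a one-sided binomial
exact test on the variant reads and depth aggregated over the patient's
matched tissue samples: under the germline null the aggregated VAF is 0.5
(heterozygous in every cell of every tissue), so a significantly *lower*
aggregated VAF marks a variant as somatic. P values are corrected with the
Benjamini-Hochberg step-up procedure and thresholded at q < 1e-5.

Sites in regions of consistently low (<15x) or high (>50x) depth across all
samples are removed before testing; both thresholds are halved on the X and
Y chromosomes of a male patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SampleMeta, VariantTable

LABEL_GERMLINE = "germline"
LABEL_SOMATIC = "somatic"
LABEL_UNCLASSIFIABLE = "unclassifiable"

RULE_LOW = "low_depth"
RULE_HIGH = "high_depth"


class UndefinedTestError(ValueError):
    """Binomial test requested with zero aggregated depth."""


@dataclass(frozen=True)
class FilterConfig:
    q_cutoff: float = 1e-5
    depth_min: float = 15.0
    depth_max: float = 50.0
    germline_vaf_null: float = 0.5
    sex_halving: bool = True
    #: aggregate over matched-reference samples only instead of all samples
    matched_only: bool = False
    #: "all" removes a site when the depth rule holds in every sample;
    #: "mean" applies the thresholds to the mean depth instead
    consistency: str = "all"

    def __post_init__(self):
        if not 0.0 < self.q_cutoff < 1.0:
            raise ValueError("q_cutoff must lie in (0, 1)")
        if not self.depth_min < self.depth_max:
            raise ValueError("depth_min must be below depth_max")
        if not 0.0 < self.germline_vaf_null < 1.0:
            raise ValueError("germline_vaf_null must lie in (0, 1)")
        if self.consistency not in ("all", "mean"):
            raise ValueError("consistency must be 'all' or 'mean'")


def binomial_germline_pvalue(alt_total: int, depth_total: int, vaf_null: float = 0.5) -> float:
    """Lower-tail exact binomial probability P(X <= alt | n=depth, p=vaf_null).

    Small values indicate the aggregated VAF sits below the germline
    expectation, i.e. evidence the variant is somatic.
    """
    if depth_total <= 0:
        raise UndefinedTestError("binomial test undefined at zero depth")
    if not 0 <= alt_total <= depth_total:
        raise ValueError("need 0 <= alt_total <= depth_total")
    return float(stats.binom.cdf(alt_total, depth_total, vaf_null))


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_germline_somatic(
    table: VariantTable, samples: SampleMeta, config: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Label every site germline / somatic / unclassifiable.

    Alt counts and depths are aggregated over the patient's matched tissue
    samples (by default all sequenced samples; restrict with
    ``config.matched_only``), tested against the VAF-0.5 null and
    BH-corrected across the testable sites.

    Returns a DataFrame indexed like the table with columns
    ``alt_total``, ``depth_total``, ``p``, ``q``, ``label``.
    """
    if config.matched_only:
        cols = samples.matched_reference_ids
        if not cols:
            raise ValueError("matched_only requested but no matched-reference samples")
    else:
        cols = samples.sample_ids
    missing = [c for c in cols if c not in table.samples]
    if missing:
        raise ValueError(f"samples missing from table: {missing}")

    alt_total = table.alt[cols].sum(axis=1).to_numpy()
    depth_total = table.depth[cols].sum(axis=1).to_numpy()
    testable = depth_total > 0

    p = np.full(table.n_sites, np.nan)
    p[testable] = stats.binom.cdf(
        alt_total[testable], depth_total[testable], config.germline_vaf_null
    )
    q = np.full(table.n_sites, np.nan)
    q[testable] = bh_correct(p[testable])

    label = np.where(q < config.q_cutoff, LABEL_SOMATIC, LABEL_GERMLINE)
    label = np.where(testable, label, LABEL_UNCLASSIFIABLE)
    return pd.DataFrame(
        {
            "alt_total": alt_total,
            "depth_total": depth_total,
            "p": p,
            "q": q,
            "label": label,
        },
        index=table.site_ids,
    )


def depth_filter(
    table: VariantTable, samples: SampleMeta, config: FilterConfig = FilterConfig()
) -> tuple[VariantTable, pd.DataFrame]:
    """Remove sites of consistently low or high depth across all samples.

    A site is removed iff its depth is below ``depth_min`` in every sample,
    or above ``depth_max`` in every sample. For X/Y sites of a male patient
    both thresholds are halved (``config.sex_halving``). Returns the
    filtered table and a removal log (site id, rule, thresholds used).
    """
    depth = table.depth.to_numpy()
    lo = np.full(table.n_sites, float(config.depth_min))
    hi = np.full(table.n_sites, float(config.depth_max))
    if config.sex_halving and samples.sex == "male":
        sexchrom = table.sites["chrom_class"].isin(["X", "Y"]).to_numpy()
        lo[sexchrom] /= 2.0
        hi[sexchrom] /= 2.0

    if config.consistency == "all":
        low = (depth < lo[:, None]).all(axis=1)
        high = (depth > hi[:, None]).all(axis=1)
    else:
        mean = depth.mean(axis=1)
        low = mean < lo
        high = mean > hi

    removed = low | high
    log = pd.DataFrame(
        {
            "rule": np.where(low, RULE_LOW, RULE_HIGH),
            "depth_min": lo,
            "depth_max": hi,
        },
        index=table.site_ids,
    )[removed]
    return table.subset(~removed), log
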