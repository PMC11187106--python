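"""CTC marker calling from qPCR ΔCq tables, cohort statistics, and ΔΔCT.

Implements the clinical arm of the analysis: gene-specific ΔCq imputation and
censoring against a healthy-donor reference, gene-positivity calling
(``ΔCq < healthy mean``, strict), the AR-or-KRT19 CTC-status rule, per-cohort
frequency tables, Fisher's exact test by exact hypergeometric enumeration,
and the comparative-CT (ΔΔCT) fold-change utility.

Conventions (documented because they are decisions, not physics):

* Missing and over-threshold ("higher than mean + 1 SD") values are both
  replaced by the gene-wise maximum observed ΔCq plus 2 cycles — both
  represent expression indistinguishable from healthy background.
* Boundary comparisons are strict exactly as worded: censoring at
  ``dcq > mean + sd``, positivity at ``dcq < mean``.
* The two-sided Fisher p-value follows the probability-mass convention (sum
  of the probabilities of all tables with the observed margins whose point
  probability is ≤ the observed one, with 1e-7 relative tie tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import contingency

from .synthetic import QPCRDataset

__all__ = [
    "HealthyReference",
    "FisherResult",
    "healthy_reference",
    "preprocess_dcq",
    "call_gene_positivity",
    "call_ctc_status",
    "cohort_frequency_table",
    "fisher_exact",
    "ddct_fold_change",
]

CTC_GENES = ("AR", "KRT19")


@dataclass(frozen=True)
class HealthyReference:
    """Per-gene healthy-donor summary used for censoring and positivity."""

    gene: str
    mean_dcq: float
    sd_dcq: float
    max_dcq: float
    n_donors: int

    def __post_init__(self) -> None:
        if self.sd_dcq < 0:
            raise ValueError("sd_dcq must be >= 0")
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def healthy_reference(
    healthy: pd.DataFrame,
    max_dcq: dict[str, float] | None = None,
    observed: pd.DataFrame | None = None,
) -> dict[str, HealthyReference]:
    """Build the per-gene reference from a donor table (donor_id, gene, dcq).

    ``max_dcq`` — the gene-wise maximum used for imputation — defaults to the
    maximum over all observed (non-missing) values in the combined run
    (donors plus, if given, the patient table ``observed``); pass a dict to
    pin it to a fixed panel constant instead.
    """
    refs: dict[str, HealthyReference] = {}
    for gene, grp in healthy.groupby("gene"):
        vals = grp["dcq"].dropna().to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"need >= 2 donor values for gene {gene!r}")
        gmax = float(vals.max())
        if observed is not None:
            obs = observed.loc[observed["gene"] == gene, "dcq"].dropna()
            if len(obs):
                gmax = max(gmax, float(obs.max()))
        if max_dcq is not None:
            gmax = float(max_dcq[gene])
        refs[str(gene)] = HealthyReference(
            gene=str(gene),
            mean_dcq=float(vals.mean()),
            sd_dcq=float(vals.std(ddof=1)),
            max_dcq=gmax,
            n_donors=int(vals.size),
        )
    return refs


def preprocess_dcq(
    dataset: QPCRDataset | pd.DataFrame,
    healthy: dict[str, HealthyReference],
) -> pd.DataFrame:
    """Impute missing and censor over-threshold ΔCq values.

    Missing values become ``max_dcq(gene) + 2`` with ``imputed_flag``;
    numeric values strictly greater than ``mean + 1·SD`` of the healthy
    donors become ``max_dcq(gene) + 2`` with ``censored_flag``.  Values at
    exactly the threshold are unchanged ("higher than" is strict).  The
    operation is idempotent: a second application changes nothing.
    """
    df = (dataset.samples if isinstance(dataset, QPCRDataset) else dataset).copy()
    for gene in df["gene"].unique():
        if gene not in healthy:
            raise KeyError(f"gene {gene!r} lacks a healthy reference")
    for gene, ref in healthy.items():
        sel = df["gene"] == gene
        sentinel = ref.max_dcq + 2.0
        missing = sel & df["dcq"].isna()
        df.loc[missing, "dcq"] = sentinel
        df.loc[missing, "imputed_flag"] = True
        already = df["imputed_flag"] | df["censored_flag"]
        over = sel & ~already & (df["dcq"] > ref.mean_dcq + ref.sd_dcq)
        df.loc[over, "dcq"] = sentinel
        df.loc[over, "censored_flag"] = True
    df["missing_flag"] = False
    return df


def call_gene_positivity(
    preprocessed: pd.DataFrame, healthy: dict[str, HealthyReference]
) -> pd.DataFrame:
    """Call per-sample per-gene positivity: positive iff ΔCq < healthy mean.

    The inequality is strict; imputed/censored sentinels (≥ gene max ≥ mean)
    compare like any number and therefore call negative.
    Returns a wide table indexed by (sample_id, cohort) with one boolean
    column per gene.
    """
    df = preprocessed.copy()
    df["positive"] = [
        dcq < healthy[g].mean_dcq for g, dcq in zip(df["gene"], df["dcq"])
    ]
    wide = df.pivot_table(
        index=["sample_id", "cohort"],
        columns="gene",
        values="positive",
        aggfunc="first",
    ).astype(bool)
    wide.columns.name = None
    return wide.reset_index()


def call_ctc_status(gene_positivity: pd.DataFrame) -> pd.DataFrame:
    """Apply the CTC-status rule: positive for AR or KRT19 (or both).

    Other gene columns (e.g. RAI2) are carried through untouched.
    """
    for g in CTC_GENES:
        if g not in gene_positivity.columns:
            raise KeyError(f"gene column {g!r} required for CTC status")
    out = gene_positivity.copy()
    out["ctc_positive"] = out["AR"] | out["KRT19"]
    return out


def cohort_frequency_table(
    statuses: pd.DataFrame,
    event: str = "ctc_positive",
    denominator: str = "all",
) -> pd.DataFrame:
    """Per-cohort frequency of an event, percentage rounded to integer.

    ``event`` is any boolean column of ``statuses`` ("ctc_positive" or a gene
    name); ``denominator`` is "all" samples or "ctc_positive" only (the RAI2
    detection rate of the study uses CTC-positive blood samples as the
    denominator).  Cohorts with an empty denominator are excluded with a
    warning.
    """
    if statuses.empty:
        raise ValueError("statuses must be non-empty")
    df = statuses
    if denominator == "ctc_positive":
        df = df[df["ctc_positive"]]
    elif denominator != "all":
        raise ValueError("denominator must be 'all' or 'ctc_positive'")
    rows = []
    for cohort, grp in df.groupby("cohort", sort=False):
        n_total = len(grp)
        if n_total == 0:  # pragma: no cover - groupby drops empty groups
            continue
        n_event = int(grp[event].sum())
        rows.append(
            {
                "cohort": cohort,
                "n_total": n_total,
                "n_event": n_event,
                "percent": int(round(100.0 * n_event / n_total)),
            }
        )
    dropped = set(statuses["cohort"].unique()) - {r["cohort"] for r in rows}
    if dropped:
        warnings.warn(f"cohorts with empty denominator excluded: {sorted(dropped)}")
    return pd.DataFrame(rows, columns=["cohort", "n_total", "n_event", "percent"])


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(top-left cell = a) for fixed margins (r1, r2) x (c1, c2)."""
    n = r1 + r2
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities that do not exceed the observed table's
    (probability-mass convention, relative tie tolerance 1e-7); computation
    is in log-space for stability.  The odds ratio is the conditional
    maximum-likelihood estimate and may be 0 or infinite.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    (a, b), (c, d) = t
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    ks = np.arange(lo, hi + 1)
    logs = np.array([_log_hypergeom_pmf(int(k), r1, r2, c1) for k in ks])
    keep = logs <= log_obs + np.log1p(1e-7)
    # log-sum-exp over the kept tables
    m = logs[keep].max()
    p = float(np.exp(m) * np.exp(logs[keep] - m).sum())
    odds = float(contingency.odds_ratio(t, kind="conditional").statistic)
    return FisherResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=odds,
        p_two_sided=min(p, 1.0),
    )


def ddct_fold_change(
    cq_target_case: float,
    cq_ref_case: float,
    cq_target_ctrl: float,
    cq_ref_ctrl: float,
) -> float:
    """Comparative-CT fold change 2^(−ΔΔCT).

    ΔΔCT = (Cq_target,case − Cq_ref,case) − (Cq_target,ctrl − Cq_ref,ctrl);
    the reference (normalization) gene is whichever Cq_ref the caller passes.
    """
    ddct = (cq_target_case - cq_ref_case) - (cq_target_ctrl - cq_ref_ctrl)
    return float(2.0 ** (-ddct))
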