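"""Discovery-stage statistics for label-free spectral counting.

Given a proteins x samples spectral-count matrix with PT (primary pancreatic
tumor) and LT (paired liver metastasis) sample groups, this module computes,
per protein:

* ``Rsc`` — the log2 protein ratio from spectral counting, with pseudo-count
  ``f``::

      Rsc = log2((n_LT + f) / (n_PT + f)) + log2((t_PT - n_PT + f) / (t_LT - n_LT + f))

  where ``n`` are the pooled per-protein counts and ``t`` the group grand
  totals.  Sign convention: positive Rsc means LT-enriched.  The reported
  fold change is ``2**|Rsc|``.

* ``NSAF`` — the normalized spectral abundance factor, the protein's
  length-normalized count divided by the within-group sum of
  length-normalized counts: ``NSAF_i = (n_i / L_i) / sum_j (n_j / L_j)``.

* ``SpI`` — the spectral index in [-1, +1], weighting each group's share of
  the protein's counts by its detection frequency across replicates::

      SpI = (c_LT / (c_PT + c_LT)) * (d_LT / m_LT)
          - (c_PT / (c_PT + c_LT)) * (d_PT / m_PT)

  with ``c`` the pooled group counts, ``d`` the number of the group's
  samples with a non-zero count and ``m`` the group size.  +1 means
  detected in every LT sample and no PT sample.

* the G-test (likelihood-ratio test) on the 2x2 table
  ``[(n_PT, n_LT), (t_PT - n_PT, t_LT - n_LT)]`` with expected counts from
  the margins, ``G = 2 * sum O * ln(O / E)`` (convention 0*ln(0/E) = 0),
  referred to the upper tail of chi-square with 1 df.

Candidates are selected by the strict rule ``|Rsc| > rsc_threshold`` AND
``p < alpha`` (defaults 1 and 0.05); Benjamini-Hochberg q-values are always
reported alongside the raw p-values but play no role in selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ProteinAnnotationTable, SpectralCountMatrix

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class PooledCounts:
    """Per-protein pooled group counts and group grand totals."""

    n_pt: pd.Series
    n_lt: pd.Series
    t_pt: int
    t_lt: int
    f: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValidationError(f"pseudo-count f must be > 0, got {self.f}")
        if int(self.n_pt.sum()) != self.t_pt or int(self.n_lt.sum()) != self.t_lt:
            raise ValidationError("group totals do not match pooled count sums")


@dataclass
class VennSummary:
    """Identification-set partition: PT-only / LT-only / shared counts."""

    pt_only: int
    lt_only: int
    shared: int

    @property
    def total(self) -> int:
        return self.pt_only + self.lt_only + self.shared

    @property
    def pt_total(self) -> int:
        return self.pt_only + self.shared

    @property
    def lt_total(self) -> int:
        return self.lt_only + self.shared

    def percentages(self, ndigits: int = 1) -> dict[str, float]:
        tot = self.total
        return {
            "pt_only": round(100 * self.pt_only / tot, ndigits),
            "lt_only": round(100 * self.lt_only / tot, ndigits),
            "shared": round(100 * self.shared / tot, ndigits),
        }

    @classmethod
    def from_set_sizes(cls, pt_total: int, lt_total: int, shared: int) -> "VennSummary":
        """Build the partition from printed set sizes (|PT|, |LT|, |PT & LT|)."""
        if shared > min(pt_total, lt_total):
            raise ValidationError("shared exceeds a set size")
        return cls(pt_only=pt_total - shared, lt_only=lt_total - shared, shared=shared)


def pool_counts(
    matrix: SpectralCountMatrix, f: float = DEFAULT_PSEUDOCOUNT
) -> PooledCounts:
    """Sum counts across all samples within each group."""
    for g in ("PT", "LT"):
        if not matrix.samples(g):
            raise ValidationError(f"group {g} has zero samples")
    n_pt = matrix.submatrix("PT").sum(axis=1)
    n_lt = matrix.submatrix("LT").sum(axis=1)
    return PooledCounts(n_pt, n_lt, int(n_pt.sum()), int(n_lt.sum()), f)


def compute_rsc(n_pt, n_lt, t_pt, t_lt, f: float = DEFAULT_PSEUDOCOUNT):
    """Log2 spectral-count ratio; positive = LT-enriched.

    Accepts scalars or aligned arrays/Series.  The pseudo-count keeps the
    ratio finite for proteins identified in only one group.
    """
    n_pt = np.asarray(n_pt, dtype=float)
    n_lt = np.asarray(n_lt, dtype=float)
    if f <= 0:
        raise ValidationError(f"pseudo-count f must be > 0, got {f}")
    if np.any(n_pt > t_pt) or np.any(n_lt > t_lt):
        raise ValidationError("per-protein count exceeds its group total")
    rsc = np.log2((n_lt + f) / (n_pt + f)) + np.log2(
        (t_pt - n_pt + f) / (t_lt - n_lt + f)
    )
    return rsc if rsc.ndim else float(rsc)


def rsc_to_fold_change(rsc):
    """Fold change on the natural scale, ``2**|Rsc|`` (always >= 1)."""
    return 2.0 ** np.abs(rsc)


def compute_nsaf(
    pooled: PooledCounts, annotations: ProteinAnnotationTable
) -> pd.DataFrame:
    """Normalized spectral abundance factor per protein per group.

    Within each group the values are non-negative and sum to 1; proteins
    with a zero pooled count get NSAF 0.  Every detected protein must have
    a length in the annotation table.
    """
    out = {}
    for name, n in (("NSAF_PT", pooled.n_pt), ("NSAF_LT", pooled.n_lt)):
        detected = n.index[n > 0]
        missing = detected.difference(annotations.lengths.index)
        if len(missing):
            raise ValidationError(
                f"missing length for detected proteins: {sorted(missing)[:10]}"
            )
        saf = pd.Series(0.0, index=n.index)
        lengths = annotations.lengths.reindex(detected)
        saf.loc[detected] = n.loc[detected] / lengths
        total = saf.sum()
        out[name] = saf / total if total > 0 else saf
    return pd.DataFrame(out)


def compute_spi(matrix: SpectralCountMatrix) -> pd.Series:
    """Spectral index per protein; NaN for proteins with no counts at all."""
    pt = matrix.submatrix("PT")
    lt = matrix.submatrix("LT")
    c_pt = pt.sum(axis=1).to_numpy(dtype=float)
    c_lt = lt.sum(axis=1).to_numpy(dtype=float)
    d_pt = (pt > 0).sum(axis=1).to_numpy(dtype=float)
    d_lt = (lt > 0).sum(axis=1).to_numpy(dtype=float)
    m_pt, m_lt = pt.shape[1], lt.shape[1]
    tot = c_pt + c_lt
    with np.errstate(invalid="ignore", divide="ignore"):
        spi = (c_lt / tot) * (d_lt / m_lt) - (c_pt / tot) * (d_pt / m_pt)
    spi[tot == 0] = np.nan  # undefined, never coerced to 0
    return pd.Series(spi, index=matrix.accessions, name="SpI")


def g_test(n_pt, n_lt, t_pt, t_lt, williams: bool = False):
    """Likelihood-ratio (G) test of a protein's count split vs the margins.

    Tests the 2x2 table [(n_PT, n_LT), (t_PT - n_PT, t_LT - n_LT)] against
    independence, with expected counts from the margins.  Returns ``(G, p)``
    with p from the upper tail of chi-square(1).  ``williams=True`` applies
    the Williams small-sample correction (off by default).
    """
    n_pt = np.asarray(n_pt, dtype=float)
    n_lt = np.asarray(n_lt, dtype=float)
    if np.any(n_pt > t_pt) or np.any(n_lt > t_lt):
        raise ValidationError("per-protein count exceeds its group total")
    if t_pt <= 0 or t_lt <= 0:
        raise ValidationError("group totals must be positive")

    obs = np.stack(
        [n_pt, n_lt, t_pt - n_pt, t_lt - n_lt], axis=-1
    )  # (..., 4): table cells row-major
    row1 = n_pt + n_lt
    row2 = (t_pt - n_pt) + (t_lt - n_lt)
    n_total = float(t_pt + t_lt)
    exp = np.stack(
        [
            row1 * t_pt / n_total,
            row1 * t_lt / n_total,
            row2 * t_pt / n_total,
            row2 * t_lt / n_total,
        ],
        axis=-1,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    g = np.maximum(g, 0.0)  # guard tiny negative round-off
    if williams:
        q = 1.0 + (
            (n_total / np.maximum(row1, 1) + n_total / np.maximum(row2, 1) - 1.0)
            * (n_total / t_pt + n_total / t_lt - 1.0)
        ) / (6.0 * n_total)
        g = g / q
    p = stats.chi2.sf(g, df=1)
    if g.ndim == 0:
        return float(g), float(p)
    return g, p


def venn_summary(matrix: SpectralCountMatrix) -> VennSummary:
    """Partition proteins by identification set (pooled group count > 0)."""
    pooled = pool_counts(matrix)
    in_pt = pooled.n_pt > 0
    in_lt = pooled.n_lt > 0
    return VennSummary(
        pt_only=int((in_pt & ~in_lt).sum()),
        lt_only=int((~in_pt & in_lt).sum()),
        shared=int((in_pt & in_lt).sum()),
    )


def differential_table(
    matrix: SpectralCountMatrix,
    annotations: ProteinAnnotationTable,
    f: float = DEFAULT_PSEUDOCOUNT,
    rsc_threshold: float = 1.0,
    alpha: float = 0.05,
    mode: str = "pooled",
    williams: bool = False,
) -> pd.DataFrame:
    """Full per-protein differential report.

    ``mode="pooled"`` (default) sums counts across all samples within a
    group before computing Rsc and the G-test; ``mode="per_case"`` averages
    per-case Rsc values over the paired cases (the G-test stays pooled, as
    it needs the full margins).
    """
    if mode not in ("pooled", "per_case"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = pool_counts(matrix, f)
    if mode == "pooled":
        rsc = compute_rsc(pooled.n_pt, pooled.n_lt, pooled.t_pt, pooled.t_lt, f)
    else:
        rsc = _per_case_rsc(matrix, f)
    rsc = pd.Series(np.asarray(rsc), index=matrix.accessions, name="Rsc")

    g, p = g_test(pooled.n_pt, pooled.n_lt, pooled.t_pt, pooled.t_lt, williams)
    q = multipletests(p, method="fdr_bh")[1]
    nsaf = compute_nsaf(pooled, annotations)
    spi = compute_spi(matrix)

    direction = np.where(rsc > 0, "LT", np.where(rsc < 0, "PT", "none"))
    table = pd.DataFrame(
        {
            "accession": matrix.accessions,
            "symbol": annotations.symbols.reindex(matrix.accessions).fillna(""),
            "n_PT": pooled.n_pt,
            "n_LT": pooled.n_lt,
            "Rsc": rsc,
            "fold_change": rsc_to_fold_change(rsc),
            "direction": direction,
            "G": g,
            "p": p,
            "q": q,
            "NSAF_PT": nsaf["NSAF_PT"],
            "NSAF_LT": nsaf["NSAF_LT"],
            "SpI": spi,
        }
    ).set_index("accession", drop=False)
    table["selected"] = (table["Rsc"].abs() > rsc_threshold) & (table["p"] < alpha)
    return table


def _per_case_rsc(matrix: SpectralCountMatrix, f: float) -> np.ndarray:
    """Mean over cases of within-case Rsc (each case's columns as totals)."""
    per_case = []
    for case in sorted(set(matrix.cases)):
        cols = [s for s in matrix.counts.columns if matrix.cases[s] == case]
        pt = [s for s in cols if matrix.groups[s] == "PT"]
        lt = [s for s in cols if matrix.groups[s] == "LT"]
        if not pt or not lt:
            continue
        n_pt = matrix.counts[pt].sum(axis=1)
        n_lt = matrix.counts[lt].sum(axis=1)
        per_case.append(
            compute_rsc(n_pt, n_lt, int(n_pt.sum()), int(n_lt.sum()), f)
        )
    if not per_case:
        raise ValidationError("no case has both a PT and an LT sample")
    return np.mean(per_case, axis=0)


def select_candidates(
    records: pd.DataFrame,
    rsc_threshold: float = 1.0,
    alpha: float = 0.05,
    spi_min: float | None = None,
    nsaf_ratio_min: float | None = None,
) -> pd.DataFrame:
    """Apply the selection rule and return candidates sorted for reporting.

    Selection is strict: ``|Rsc| > rsc_threshold`` AND ``p < alpha``.
    Optional secondary filters (off by default): ``spi_min`` requires
    ``|SpI| >= spi_min`` with the sign agreeing with Rsc; ``nsaf_ratio_min``
    requires the NSAF ratio in the direction of change to be at least the
    given value.  Output is sorted by |Rsc| descending, ties broken by
    ascending p then accession.
    """
    sel = (records["Rsc"].abs() > rsc_threshold) & (records["p"] < alpha)
    if spi_min is not None:
        agree = np.sign(records["SpI"].fillna(0)) == np.sign(records["Rsc"])
        sel &= agree & (records["SpI"].abs() >= spi_min)
    if nsaf_ratio_min is not None:
        eps = np.finfo(float).tiny
        ratio = np.where(
            records["Rsc"] > 0,
            records["NSAF_LT"] / np.maximum(records["NSAF_PT"], eps),
            records["NSAF_PT"] / np.maximum(records["NSAF_LT"], eps),
        )
        sel &= ratio >= nsaf_ratio_min
    out = records[sel].copy()
    out["selected"] = True
    out["_abs_rsc"] = out["Rsc"].abs()
    out.index.name = None  # the accession column drives the tie-break
    out = out.sort_values(
        ["_abs_rsc", "p", "accession"], ascending=[False, True, True]
    ).drop(columns="_abs_rsc")
    out.index.name = "accession"
    return out
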