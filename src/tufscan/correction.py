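"""Per-sample GC/CpG wave correction of LRR intensities.

The correction model regresses each sample's LRR on centered polynomial
GC and CpG content terms at multiple window scales plus within-chip
stratum offsets:

    LRR_i ~ intercept + sum_w sum_p b_GC(w,p) (g_wi - mean g_w)^p
                      + sum_w sum_p b_CpG(w,p) (c_wi - mean c_w)^p
                      + stratum(i) offsets + error

fit by ordinary least squares, one model per sample (the wave phenotype is
sample-specific). The corrected LRR is the residual re-centered to the
sample's pre-correction mean. Per-term Z scores (coefficient / SE) drive the
extreme-sample classification; the classical threshold is |Z| > 30.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .content import WindowContentMatrix

__all__ = [
    "QuantileNormalizer",
    "quantile_normalize",
    "CorrectionModel",
    "WaveCorrector",
    "fit_wave_model",
    "correct_lrr",
    "variance_report",
    "classify_extreme_samples",
]


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force every sample's LRR distribution onto a common reference.

    The reference is the mean of the samples' sorted value vectors; each
    sample's values are replaced by the reference value at their rank. Tied
    values receive the average of the reference values their ranks span, so
    the mapping is permutation-stable.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.reference_ = np.sort(X.to_numpy(), axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = self._validate(X, n_min=1)
        ref = self.reference_
        if X.shape[1] != len(ref):
            raise ValueError("column count differs from the fitted reference")
        out = np.empty(X.shape)
        vals = X.to_numpy()
        for i in range(X.shape[0]):
            row = vals[i]
            order = np.argsort(row, kind="stable")
            assigned = np.empty(len(row))
            assigned[order] = ref
            # ties: average the reference values the tied ranks span
            s = pd.Series(assigned)
            out[i] = s.groupby(row, sort=False).transform("mean").to_numpy()
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    @staticmethod
    def _validate(X, n_min: int = 2) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[0] < n_min:
            raise ValueError(f"need at least {n_min} samples")
        if X.isna().to_numpy().any():
            raise ValueError(
                "missing LRR values: impute or drop probes upstream before "
                "quantile normalization"
            )
        return X


def quantile_normalize(matrix) -> pd.DataFrame:
    """Quantile-normalize a samples x probes matrix (see QuantileNormalizer)."""
    lrr = matrix.lrr if hasattr(matrix, "lrr") else matrix
    return QuantileNormalizer().fit_transform(lrr)


@dataclass
class CorrectionModel:
    """One sample's fitted wave-correction regression."""

    sample_id: str
    terms: list
    params: pd.Series
    bse: pd.Series
    z: pd.Series
    variance_pre: float
    variance_post: float
    r_squared: float
    aliased: list = field(default_factory=list)

    @property
    def prop_variance_explained(self) -> float:
        return self.r_squared

    def z_for(
        self, metric: Optional[str] = None, degree: Optional[int] = None
    ) -> pd.Series:
        """Z scores of the content terms, filtered by metric and/or degree."""
        keep = {}
        for t in self.terms:
            if not (isinstance(t, tuple) and len(t) == 3):
                continue
            m, w, p = t
            if metric is not None and m != metric:
                continue
            if degree is not None and p != degree:
                continue
            key = f"{m}_{w}_d{p}"
            if key in self.z.index:
                keep[t] = self.z[key]
        return pd.Series(keep, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "term": self.params.index,
                "coefficient": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "z": self.z.to_numpy(),
            }
        )


def _term_name(term) -> str:
    if isinstance(term, tuple) and len(term) == 3:
        m, w, p = term
        return f"{m}_{w}_d{p}"
    return str(term)


class WaveCorrector(BaseEstimator, TransformerMixin):
    """Per-sample OLS wave correction, transform = corrected LRR.

    Parameters
    ----------
    content : WindowContentMatrix or DataFrame
        Probe-level GC/CpG fractions; the fixed design shared by all samples.
    strata : Series, optional
        Per-probe chip-stratum labels, entering as indicator offsets
        (first stratum is the reference level).
    degree : int
        Polynomial degree of the content terms (covariates are centered
        across probes before expansion).
    windows : sequence of int, optional
        Subset of window sizes to use; defaults to all columns of ``content``.
    """

    def __init__(self, content, strata=None, degree: int = 2, windows=None):
        self.content = content
        self.strata = strata
        self.degree = degree
        self.windows = windows

    # -- design ----------------------------------------------------------
    def _content_frame(self) -> pd.DataFrame:
        c = self.content
        return c.values if isinstance(c, WindowContentMatrix) else c

    def _build_design(self):
        cf = self._content_frame()
        windows = self.windows
        cols = []
        terms = []
        for metric, w in cf.columns:
            if windows is not None and int(w) not in {int(x) for x in windows}:
                continue
            x = cf[(metric, w)].to_numpy(dtype=float)
            xc = x - np.nanmean(x)
            for p in range(1, self.degree + 1):
                cols.append(xc**p)
                terms.append((metric, int(w), p))
        design = [np.ones(len(cf))]
        names = ["intercept"]
        design += cols
        names += [_term_name(t) for t in terms]
        if self.strata is not None:
            strata = pd.Series(self.strata)
            levels = list(dict.fromkeys(strata))
            for lev in levels[1:]:  # first level is the reference
                design.append((strata == lev).to_numpy(dtype=float))
                names.append(f"stratum[{lev}]")
                terms.append(f"stratum[{lev}]")
        D = np.column_stack(design)
        return D, names, terms

    @staticmethod
    def _drop_aliased(D: np.ndarray, names: list):
        """Drop linearly dependent columns via pivoted QR, keeping order."""
        rank = np.linalg.matrix_rank(D)
        if rank == D.shape[1]:
            return D, names, []
        keep: list[int] = []
        for j in range(D.shape[1]):
            trial = D[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        dropped = [names[j] for j in range(D.shape[1]) if j not in keep]
        warnings.warn(
            f"rank-deficient design: dropping aliased terms {dropped}",
            stacklevel=3,
        )
        return D[:, keep], [names[j] for j in keep], dropped

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None):
        """Fit one OLS model per sample.

        ``X`` is a samples x probes DataFrame (or a 1-D Series for a single
        sample); probe order must match the content matrix.
        """
        X = self._coerce(X)
        cf = self._content_frame()
        if X.shape[1] != len(cf):
            raise ValueError(
                f"LRR has {X.shape[1]} probes but content has {len(cf)}"
            )
        D, names, terms = self._build_design()
        D, names, dropped = self._drop_aliased(D, names)
        n, k = D.shape
        if n < k + 2:
            raise ValueError(f"too few probes ({n}) for {k} design terms")
        if n < 10 * k:
            warnings.warn(
                f"only {n} probes for {k} terms; estimates may be unstable",
                stacklevel=2,
            )
        self.design_ = D
        self.term_names_ = names
        self.terms_ = [t for t in terms if _term_name(t) in names]
        self.aliased_ = dropped
        models = []
        for sid, row in X.iterrows():
            y_vec = row.to_numpy(dtype=float)
            res = sm.OLS(y_vec, D).fit()
            params = pd.Series(res.params, index=names)
            bse = pd.Series(res.bse, index=names)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = params / bse
            var_pre = float(np.var(y_vec, ddof=1))
            var_post = float(np.var(res.resid, ddof=1))
            r2 = float(res.rsquared) if var_pre > 0 else 0.0
            models.append(
                CorrectionModel(
                    sample_id=str(sid),
                    terms=list(self.terms_),
                    params=params,
                    bse=bse,
                    z=z,
                    variance_pre=var_pre,
                    variance_post=var_post,
                    r_squared=r2,
                    aliased=list(dropped),
                )
            )
        self.models_ = models
        self.sample_ids_ = list(X.index)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Corrected LRR: residual re-centered to each sample's mean."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "models_")
        X = self._coerce(X)
        if X.shape[1] != self.design_.shape[0]:
            raise ValueError("probe count differs from the fitted design")
        by_id = {m.sample_id: m for m in self.models_}
        out = np.empty(X.shape)
        for i, (sid, row) in enumerate(X.iterrows()):
            model = by_id.get(str(sid))
            if model is None:
                raise KeyError(f"sample {sid!r} was not fitted")
            y = row.to_numpy(dtype=float)
            fitted = self.design_ @ model.params.to_numpy()
            out[i] = y - fitted + y.mean()
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    @staticmethod
    def _coerce(X) -> pd.DataFrame:
        if hasattr(X, "lrr"):
            X = X.lrr
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError("LRR must be finite")
        return X


def fit_wave_model(
    lrr_s, content, strata=None, degree: int = 2, sample_id: str = "sample"
) -> CorrectionModel:
    """Fit the wave-correction OLS for a single sample's LRR vector."""
    series = pd.Series(np.asarray(lrr_s, dtype=float), name=sample_id)
    wc = WaveCorrector(content, strata=strata, degree=degree).fit(series)
    return wc.models_[0]


def correct_lrr(model: CorrectionModel, lrr_s, content, strata=None) -> np.ndarray:
    """Corrected LRR for one sample given its fitted model."""
    wc = WaveCorrector(content, strata=strata, degree=max(
        (t[2] for t in model.terms if isinstance(t, tuple)), default=1
    ))
    D, names, _ = wc._build_design()
    D, names, _ = wc._drop_aliased(D, names)
    if names != list(model.params.index):
        raise ValueError("design does not match the fitted model terms")
    y = np.asarray(lrr_s, dtype=float)
    if len(y) != D.shape[0]:
        raise ValueError("LRR length does not match the design")
    return y - D @ model.params.to_numpy() + y.mean()


def variance_report(models: Iterable[CorrectionModel]) -> pd.DataFrame:
    """Pre/post correction LRR variance per sample (scatter-ready)."""
    rows = [
        {
            "sample_id": m.sample_id,
            "variance_pre": m.variance_pre,
            "variance_post": m.variance_post,
            "variance_ratio": m.variance_post / m.variance_pre
            if m.variance_pre > 0
            else np.nan,
            "prop_variance_explained": m.r_squared,
        }
        for m in models
    ]
    return pd.DataFrame(rows)


def classify_extreme_samples(
    models: Iterable[CorrectionModel],
    z_threshold: float = 30.0,
    metric: str = "GC",
    degree: Optional[int] = None,
    selector: Optional[Callable[[CorrectionModel], tuple]] = None,
) -> pd.DataFrame:
    """Label samples positive / negative / null by their most extreme wave Z.

    The default statistic is the maximum-|Z| GC content term (any window);
    a custom ``selector`` may return ``(term, z)`` per model instead.
    """
    models = list(models)
    if len({tuple(_term_name(t) for t in m.terms) for m in models}) > 1:
        raise ValueError("models do not share a term structure")
    rows = []
    for m in models:
        if selector is not None:
            term, z = selector(m)
        else:
            zs = m.z_for(metric=metric, degree=degree)
            if zs.empty:
                raise ValueError(f"no {metric} terms in model {m.sample_id}")
            term = zs.abs().idxmax()
            z = float(zs[term])
        if z > z_threshold:
            label = "positive"
        elif z < -z_threshold:
            label = "negative"
        else:
            label = "null"
        rows.append(
            {"sample_id": m.sample_id, "label": label, "term": _term_name(term), "z": z}
        )
    return pd.DataFrame(rows)


def models_to_tsv(models: Iterable[CorrectionModel], path) -> None:
    """Long-format dump of every model's terms, coefficients, SEs and Z."""
    pd.concat([m.to_frame() for m in models], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
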