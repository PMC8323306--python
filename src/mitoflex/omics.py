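"""Statistical procedures for lipidomics and proteomics tables.

Pipeline pieces: class-internal-standard normalization, the differential
abundance screen (log2 + mean-centring + per-analyte Student's t-tests +
FDR at Q=5% + fold-change gates 1.5/0.66), the diet-response scatter
normalization, Pearson correlation against a per-sample index, and a
two-factor (age x diet) screen with Tukey-corrected pairwise contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

AGES = ("young", "old")
DIETS = ("LFD", "HFD")

#: significance gates of the differential screen
Q_THRESHOLD = 0.05
FC_UP = 1.5
FC_DOWN = 0.66

_FDR_METHODS = {"bh": "fdr_bh", "two-stage": "fdr_tsbh"}


@dataclass
class OmicsTable:
    """Analyte x sample matrix with group labels.

    ``values``: DataFrame, analytes as rows, samples as columns.
    ``samples``: DataFrame indexed by sample with 'age' and 'diet' columns.
    ``classes``: optional Series mapping analyte -> class label (lipids).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    classes: Optional[pd.Series] = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ConfigurationError(f"duplicate analyte identifiers: {list(dupes)}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ConfigurationError(f"samples without group labels: {sorted(missing)}")
        for col in ("age", "diet"):
            if col not in self.samples.columns:
                raise ConfigurationError(f"sample sheet lacks {col!r} column")
        if self.samples.loc[list(self.values.columns), ["age", "diet"]].isna().any().any():
            raise ConfigurationError("incomplete group labels")
        if (self.values.to_numpy() < 0).any():
            raise DomainError("negative intensities")
        if self.classes is not None:
            missing_cls = set(self.values.index) - set(self.classes.index)
            if missing_cls:
                raise ConfigurationError(
                    f"analytes without class annotation: {sorted(missing_cls)[:5]}..."
                )

    def columns_for(self, age: Optional[str] = None, diet: Optional[str] = None):
        mask = pd.Series(True, index=self.samples.index)
        if age is not None:
            mask &= self.samples["age"] == age
        if diet is not None:
            mask &= self.samples["diet"] == diet
        keep = [c for c in self.values.columns if mask.get(c, False)]
        return keep


def normalize_to_class_standard(
    table: OmicsTable, standards: Mapping[str, float]
) -> OmicsTable:
    """Divide every analyte by its class's internal-standard intensity.

    Classes without a standard are normalized to the mean of all available
    standards.  A zero standard intensity is an error naming the class.
    """
    if table.classes is None:
        raise ConfigurationError("class annotations required for normalization")
    for cls, value in standards.items():
        if value == 0:
            raise DomainError(f"zero standard intensity for class {cls!r}")
        if value < 0:
            raise DomainError(f"negative standard intensity for class {cls!r}")
    if not standards:
        raise ConfigurationError("no standards provided")
    fallback = float(np.mean(list(standards.values())))
    divisors = table.classes.loc[table.values.index].map(
        lambda cls: standards.get(cls, fallback)
    )
    values = table.values.div(divisors.astype(float), axis=0)
    return OmicsTable(values=values, samples=table.samples, classes=table.classes)


def _prepare_log2(values: pd.DataFrame, zero_policy: str) -> pd.DataFrame:
    """log2 with documented zero handling: 'half-min' replaces zeros by half
    the analyte's smallest positive value ('error' refuses zeros)."""
    arr = values.to_numpy(dtype=float).copy()
    if (arr == 0).any():
        if zero_policy == "error":
            raise DomainError("zero intensities cannot be log-transformed")
        if zero_policy != "half-min":
            raise ConfigurationError(f"unknown zero policy {zero_policy!r}")
        for i in range(arr.shape[0]):
            row = arr[i]
            zero = row == 0
            if zero.any():
                positive = row[row > 0]
                if positive.size == 0:
                    raise DomainError(
                        f"analyte {values.index[i]!r} is all-zero; cannot log-transform"
                    )
                row[zero] = positive.min() / 2.0
                log.warning(
                    "replaced %d zero(s) of analyte %s by half-minimum",
                    int(zero.sum()), values.index[i],
                )
    return pd.DataFrame(np.log2(arr), index=values.index, columns=values.columns)


def _welchless_t(a: np.ndarray, b: np.ndarray):
    """Vectorised two-sample Student's t (equal variance) along axis 1.

    Degenerate rows (zero pooled variance): p = 1 when the means agree
    (by convention, logged), p = 0 when they differ (perfect separation).
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    if degenerate.any():
        same = degenerate & (np.abs(diff) < 1e-300)
        sep = degenerate & ~same
        t[same], p[same] = 0.0, 1.0
        t[sep] = np.sign(diff[sep]) * np.inf
        p[sep] = 0.0
        if same.any():
            log.warning("%d analyte(s) with degenerate variance: p set to 1",
                        int(same.sum()))
    return t, p


def differential(
    table: OmicsTable,
    age: str,
    fdr: str = "bh",
    zero_policy: str = "half-min",
) -> pd.DataFrame:
    """HFD-vs-LFD differential abundance within one age stratum.

    Per analyte: log2 transform, mean-centre across the stratum, Student's
    t-test HFD vs LFD, FDR adjustment (Q = 5%; 'bh' step-up by default,
    'two-stage' adaptive step-up optional), linear-scale fold change of the
    group means, and the combined significance flag
    (q < 0.05) AND (FC >= 1.5 OR FC <= 0.66).
    """
    if age not in AGES:
        raise DomainError(f"age must be one of {AGES}, got {age!r}")
    if fdr not in _FDR_METHODS:
        raise ConfigurationError(f"fdr must be one of {sorted(_FDR_METHODS)}")
    lfd = table.columns_for(age=age, diet="LFD")
    hfd = table.columns_for(age=age, diet="HFD")
    if len(lfd) < 2 or len(hfd) < 2:
        raise DomainError(f"need >= 2 samples per diet in the {age} stratum")

    stratum = table.values[lfd + hfd]
    logged = _prepare_log2(stratum, zero_policy)
    centred = logged.sub(logged.mean(axis=1), axis=0)  # per-analyte location shift

    t, p = _welchless_t(centred[lfd].to_numpy(), centred[hfd].to_numpy())
    _, q, _, _ = multipletests(p, alpha=Q_THRESHOLD, method=_FDR_METHODS[fdr])

    mean_lfd = stratum[lfd].mean(axis=1)
    mean_hfd = stratum[hfd].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_hfd / mean_lfd
    flag = (q < Q_THRESHOLD) & ((fc >= FC_UP) | (fc <= FC_DOWN))
    out = pd.DataFrame(
        {
            "mean_lfd": mean_lfd,
            "mean_hfd": mean_hfd,
            "fold_change": fc,
            "t": t,
            "p": p,
            "q": q,
            "significant": flag.to_numpy(),
        },
        index=stratum.index,
    )
    out["direction"] = np.sign(np.log(out["fold_change"].replace(0, np.nan)))
    out.attrs["fdr_method"] = fdr
    out.attrs["age"] = age
    return out


def diet_response_scatter(table: OmicsTable) -> pd.DataFrame:
    """Normalized (LFD mean, HFD mean) per analyte and age.

    Each analyte is divided by its mean over all animals; points on the
    identity line indicate no diet effect.  Analytes with a zero grand mean
    are dropped with a warning.
    """
    grand = table.values.mean(axis=1)
    keep = grand > 0
    if (~keep).any():
        log.warning("dropping %d analyte(s) with zero grand mean", int((~keep).sum()))
    norm = table.values.loc[keep].div(grand[keep], axis=0)
    rows = []
    for age in AGES:
        lfd = table.columns_for(age=age, diet="LFD")
        hfd = table.columns_for(age=age, diet="HFD")
        if not lfd or not hfd:
            continue
        frame = pd.DataFrame(
            {
                "age": age,
                "lfd_mean": norm[lfd].mean(axis=1),
                "hfd_mean": norm[hfd].mean(axis=1),
            },
            index=norm.index,
        )
        rows.append(frame.reset_index(names="analyte"))
    return pd.concat(rows, ignore_index=True)


def correlate_with_index(
    table: OmicsTable, index: pd.Series
) -> pd.DataFrame:
    """Pearson r and two-sided p of every analyte against a per-sample index
    (samples pooled over all groups).  Zero-variance vectors are flagged
    undefined rather than returned as silent NaN."""
    common = [c for c in table.values.columns if c in index.index]
    if len(common) < 3:
        raise DomainError("need >= 3 paired observations")
    x = index.loc[common].to_numpy(dtype=float)
    y = table.values[common].to_numpy(dtype=float)
    n = len(common)
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=1))
    defined = (sx > 0) & (sy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    exact = defined & (np.abs(r) >= 1.0)
    p[exact] = 0.0
    r[~defined] = np.nan
    p[~defined] = np.nan
    return pd.DataFrame(
        {"r": r, "p": p, "n": n, "defined": defined}, index=table.values.index
    )


def _rss(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of y regressed on columns of x."""
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ beta
    return (resid ** 2).sum(axis=0)


def factorial_screen(
    table: OmicsTable,
    log2: bool = False,
    tukey: bool = True,
) -> pd.DataFrame:
    """Two-factor (age x diet) fixed-effects screen per analyte.

    Marginal (Type-II) sums of squares handle the unbalanced 2x2 design;
    effect directions are the signs of the marginal mean differences
    (HFD - LFD, old - young).  With ``tukey=True``, Tukey-Kramer pairwise
    p-values for the diet contrast within each age (and age contrast within
    each diet) are added, using the studentized range over the four cells.
    """
    cells = {}
    for age in AGES:
        for diet in DIETS:
            cols = table.columns_for(age=age, diet=diet)
            if not cols:
                raise DomainError(f"empty cell: {age}/{diet}")
            cells[(age, diet)] = cols

    y = table.values.to_numpy(dtype=float)
    if log2:
        y = _prepare_log2(table.values, "half-min").to_numpy()
    columns = list(table.values.columns)
    a = np.array([table.samples.loc[c, "age"] == "old" for c in columns], float)
    d = np.array([table.samples.loc[c, "diet"] == "HFD" for c in columns], float)
    n = len(columns)
    one = np.ones(n)

    x_full = np.column_stack([one, a, d, a * d])
    x_add = np.column_stack([one, a, d])
    x_age = np.column_stack([one, a])
    x_diet = np.column_stack([one, d])

    rss_full = _rss(y, x_full)
    rss_add = _rss(y, x_add)
    rss_age = _rss(y, x_age)
    rss_diet = _rss(y, x_diet)

    df_err = n - 4
    if df_err <= 0:
        raise DomainError("not enough samples for the factorial model")
    mse = rss_full / df_err

    def f_test(ss):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.maximum(ss, 0.0) / mse
        return stats.f.sf(f, 1, df_err)

    p_age = f_test(rss_diet - rss_add)   # SS(age | diet)
    p_diet = f_test(rss_age - rss_add)   # SS(diet | age)
    p_int = f_test(rss_add - rss_full)

    means = {key: y[:, [columns.index(c) for c in cols]].mean(axis=1)
             for key, cols in cells.items()}
    diet_diff = (means[("young", "HFD")] + means[("old", "HFD")]
                 - means[("young", "LFD")] - means[("old", "LFD")]) / 2.0
    age_diff = (means[("old", "LFD")] + means[("old", "HFD")]
                - means[("young", "LFD")] - means[("young", "HFD")]) / 2.0

    out = pd.DataFrame(
        {
            "p_age": p_age,
            "p_diet": p_diet,
            "p_interaction": p_int,
            "dir_age": np.sign(age_diff),
            "dir_diet": np.sign(diet_diff),
        },
        index=table.values.index,
    )
    for key, cols in cells.items():
        out[f"mean_{key[0]}_{key[1]}"] = means[key]

    if tukey:
        counts = {key: len(cols) for key, cols in cells.items()}

        def tukey_p(key1, key2):
            diff = np.abs(means[key1] - means[key2])
            se = np.sqrt(mse / 2.0 * (1.0 / counts[key1] + 1.0 / counts[key2]))
            with np.errstate(divide="ignore", invalid="ignore"):
                qstat = diff / se
            p = stats.studentized_range.sf(qstat, 4, df_err)
            return np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p)

        out["p_tukey_diet_young"] = tukey_p(("young", "HFD"), ("young", "LFD"))
        out["p_tukey_diet_old"] = tukey_p(("old", "HFD"), ("old", "LFD"))
        out["p_tukey_age_lfd"] = tukey_p(("old", "LFD"), ("young", "LFD"))
        out["p_tukey_age_hfd"] = tukey_p(("old", "HFD"), ("young", "HFD"))
    return out
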