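"""Peak-table QC and normalization chain.

Order of operations is fixed and mirrors standard untargeted GC-MS
practice: contaminant/prevalence filtering → internal-standard (IS)
assignment on pooled-QC injections → per-injection IS ratio normalization
→ QC-median batch centering → half-minimum imputation of below-LOD cells
→ QC CV filtering → log z-scores over study samples.

Below-LOD cells are represented as NaN throughout; they are never zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger("mwaskit")

#: Feature fates recorded by the pipeline.
FATE_RETAINED = "retained"
FATE_BLANK = "dropped_blank"
FATE_PREVALENCE = "dropped_prevalence"
FATE_R2 = "dropped_r2"
FATE_CV = "dropped_cv"
FATE_ALL_BELOW_LOD = "dropped_all_below_lod"
FATE_ALL_BELOW_LOD_QC = "dropped_all_below_lod_qc"
FATE_ZERO_VARIANCE = "dropped_zero_variance"


class PeakTableError(ValueError):
    """Structural problem in a peak table."""


@dataclass
class PeakTable:
    """Injection-by-feature abundances with IS channels and annotations.

    All three frames are indexed by ``sample_id`` in injection order.
    ``abundance`` holds non-negative peak areas with NaN marking below-LOD
    cells; ``is_channels`` holds the spiked internal-standard signals
    (NaN in negative-control blanks, which receive no spike).
    """
    samples: pd.DataFrame       # columns: injection_order, batch, sample_type
    abundance: pd.DataFrame
    is_channels: pd.DataFrame
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.samples.index.equals(self.abundance.index)
                and self.samples.index.equals(self.is_channels.index)):
            raise PeakTableError("sample index mismatch across frames")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise PeakTableError(f"duplicate sample_id {dup!r}")
        if self.abundance.columns.has_duplicates:
            raise PeakTableError("feature ids are not unique")
        bad = set(self.samples["sample_type"]) - {"study", "qc", "blank"}
        if bad:
            raise PeakTableError(f"unknown sample_type values: {sorted(bad)}")
        vals = self.abundance.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise PeakTableError("negative abundances present")

    # -- convenience masks -------------------------------------------------
    def rows_of(self, sample_type: str) -> pd.Index:
        return self.samples.index[self.samples["sample_type"] == sample_type]

    @property
    def features(self) -> pd.Index:
        return self.abundance.columns

    def replace(self, **kw) -> "PeakTable":
        data = {"samples": self.samples, "abundance": self.abundance,
                "is_channels": self.is_channels, "provenance": self.provenance}
        data.update(kw)
        return PeakTable(**data)


@dataclass
class NormalizedMatrix:
    """Post-QC metabolite z-scores with per-feature provenance.

    ``z``: study-subject × retained-metabolite z-scores (each column mean 0,
    sample SD 1 over study samples).  ``feature_report`` records every input
    feature's fate, chosen IS, R², QC CV (%) and imputed-cell count;
    ``batch_factors`` holds the multiplicative QC-median correction factors.
    """
    z: pd.DataFrame
    feature_report: pd.DataFrame
    batch_factors: pd.DataFrame
    qc_cv_summary: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# 1. blank / prevalence filtering
# --------------------------------------------------------------------------

def filter_features(pt: PeakTable, prevalence_min: float = 0.05,
                    blank_ratio_max: float = 0.5,
                    ) -> tuple[PeakTable, pd.Series]:
    """Drop contaminant and rare features.

    A feature is a contaminant when its mean blank signal (absent cells
    counted as zero) exceeds ``blank_ratio_max`` of its mean study signal —
    a blank-ratio heuristic standing in for "identified by comparison with
    negative control samples".  A feature is rare when it is detected
    (above LOD) in fewer than ``prevalence_min`` of all non-blank
    injections.  Returns the filtered table and a fate Series for the
    dropped features.
    """
    blanks = pt.rows_of("blank")
    study = pt.rows_of("study")
    nonblank = pt.samples.index[pt.samples["sample_type"] != "blank"]

    fates = pd.Series(dtype=object)
    drop: list[str] = []

    if len(blanks) == 0:
        logger.warning("no blank injections: contaminant filtering skipped")
        contaminant = pd.Series(False, index=pt.features)
    else:
        blank_mean = pt.abundance.loc[blanks].fillna(0.0).mean(axis=0)
        study_mean = pt.abundance.loc[study].fillna(0.0).mean(axis=0)
        contaminant = (blank_mean > 0) & (blank_mean > blank_ratio_max * study_mean)

    prevalence = pt.abundance.loc[nonblank].notna().mean(axis=0)

    for f in pt.features:
        if contaminant[f]:
            fates[f] = FATE_BLANK
            drop.append(f)
        elif prevalence[f] < prevalence_min:
            fates[f] = FATE_PREVALENCE
            drop.append(f)
    kept = [f for f in pt.features if f not in set(drop)]
    logger.info("filter_features: %d contaminant, %d low-prevalence, %d kept",
                int((fates == FATE_BLANK).sum()),
                int((fates == FATE_PREVALENCE).sum()), len(kept))
    return pt.replace(abundance=pt.abundance[kept]), fates


# --------------------------------------------------------------------------
# 2. internal-standard assignment
# --------------------------------------------------------------------------

def assign_internal_standards(pt: PeakTable, r2_min: float = 0.75,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choose, per feature, the IS with the highest R² in QC injections.

    R² is the squared Pearson correlation between log feature abundance and
    log IS abundance across QC injections (pairwise-complete).  A feature
    whose best R² falls below ``r2_min`` is marked ``omitted``; a feature
    with no observed QC value is marked omitted with an all-below-LOD note.
    Ties are broken by IS column order; an IS with zero variance in QCs
    scores R² = 0 by decision.

    Returns ``(assignment, r2_matrix)`` where assignment has columns
    ``chosen_is`` (IS id or "omitted"), ``r2`` and ``note``.
    """
    qc = pt.rows_of("qc")
    if len(qc) < 3:
        raise PeakTableError(
            f"IS assignment needs >= 3 QC injections, found {len(qc)}")
    log_is = np.log(pt.is_channels.loc[qc].where(pt.is_channels.loc[qc] > 0))
    log_ab = np.log(pt.abundance.loc[qc])

    r2 = pd.DataFrame(np.nan, index=pt.features, columns=pt.is_channels.columns)
    rows = []
    for f in pt.features:
        y = log_ab[f]
        if y.notna().sum() == 0:
            rows.append((f, "omitted", np.nan, "all_below_lod_qc"))
            continue
        for k in pt.is_channels.columns:
            pair = pd.concat([y, log_is[k]], axis=1).dropna()
            if len(pair) < 3:
                r2.loc[f, k] = 0.0
                continue
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if a.std() == 0 or b.std() == 0:
                r2.loc[f, k] = 0.0
            else:
                r2.loc[f, k] = float(np.corrcoef(a, b)[0, 1] ** 2)
        best = r2.loc[f].to_numpy(float)
        j = int(np.argmax(best))          # first maximum -> IS-order tie-break
        if best[j] < r2_min:
            rows.append((f, "omitted", float(best[j]), "max_r2_below_threshold"))
        else:
            rows.append((f, str(pt.is_channels.columns[j]), float(best[j]), ""))
    assign = pd.DataFrame(rows, columns=["feature", "chosen_is", "r2", "note"]
                          ).set_index("feature")
    return assign, r2


# --------------------------------------------------------------------------
# 3. IS normalization
# --------------------------------------------------------------------------

def normalize_by_is(pt: PeakTable, assign: pd.DataFrame,
                    ) -> tuple[PeakTable, pd.Series]:
    """Divide each feature by its chosen IS within the same injection.

    Omitted features are removed.  A cell whose IS value is missing or
    non-positive becomes below-LOD (NaN); the per-feature count of such
    cells is returned.  Below-LOD flags in the feature itself propagate.
    """
    kept = assign.index[assign["chosen_is"] != "omitted"]
    out = {}
    lost = pd.Series(0, index=kept, dtype=int)
    for f in kept:
        is_vals = pt.is_channels[assign.loc[f, "chosen_is"]]
        denom = is_vals.where(is_vals > 0)
        ratio = pt.abundance[f] / denom
        lost[f] = int((pt.abundance[f].notna() & denom.isna()).sum())
        out[f] = ratio
    if lost.sum():
        logger.warning("normalize_by_is: %d cells set below-LOD "
                       "(IS missing or zero)", int(lost.sum()))
    abundance = pd.DataFrame(out, index=pt.samples.index)[list(kept)]
    return pt.replace(abundance=abundance), lost


# --------------------------------------------------------------------------
# 4. QC-median batch centering
# --------------------------------------------------------------------------

def median_center_batches(pt: PeakTable) -> tuple[PeakTable, pd.DataFrame]:
    """Align batches multiplicatively on QC medians.

    Per feature and batch, factor = (median over QC injections of all
    batches) / (median over QC injections of that batch); every injection
    in the batch is multiplied by the factor, so each batch's QC median
    lands exactly on the global QC median.  A batch with no usable QC value
    for a feature gets factor 1 with a warning.
    """
    qc = pt.rows_of("qc")
    batches = pd.unique(pt.samples["batch"])
    global_med = pt.abundance.loc[qc].median(axis=0, skipna=True)
    factors = pd.DataFrame(1.0, index=pt.features, columns=batches)
    corrected = pt.abundance.copy()
    n_defaulted = 0
    for b in batches:
        qc_b = qc[pt.samples.loc[qc, "batch"] == b]
        med_b = pt.abundance.loc[qc_b].median(axis=0, skipna=True)
        fac = global_med / med_b
        bad = ~np.isfinite(fac)
        n_defaulted += int(bad.sum())
        fac[bad] = 1.0
        factors[b] = fac
        rows = pt.samples.index[pt.samples["batch"] == b]
        corrected.loc[rows] = corrected.loc[rows] * fac
    if n_defaulted:
        logger.warning("median_center_batches: %d feature×batch cells had no "
                       "usable QC; factor defaulted to 1", n_defaulted)
    return pt.replace(abundance=corrected), factors


# --------------------------------------------------------------------------
# 5. half-minimum imputation of below-LOD cells
# --------------------------------------------------------------------------

def impute_half_min(pt: PeakTable) -> tuple[PeakTable, pd.Series, pd.Series]:
    """Assign below-LOD cells half the feature's minimum observed value.

    The minimum is taken over all non-blank injections after batch
    correction; blank rows are left untouched.  Features with no observed
    value anywhere are dropped with an all-below-LOD fate.  Returns
    ``(table, n_imputed_per_feature, fates_of_dropped)``.
    """
    nonblank = pt.samples.index[pt.samples["sample_type"] != "blank"]
    block = pt.abundance.loc[nonblank]
    mins = block.min(axis=0, skipna=True)
    dead = mins.index[mins.isna()]
    fates = pd.Series(FATE_ALL_BELOW_LOD, index=dead, dtype=object)
    kept = [f for f in pt.features if f not in set(dead)]
    abundance = pt.abundance[kept].copy()
    n_imputed = pd.Series(0, index=kept, dtype=int)
    for f in kept:
        mask = abundance[f].isna() & abundance.index.isin(nonblank)
        n_imputed[f] = int(mask.sum())
        abundance.loc[mask, f] = 0.5 * mins[f]
    return pt.replace(abundance=abundance), n_imputed, fates


# --------------------------------------------------------------------------
# 6. QC CV filter
# --------------------------------------------------------------------------

def qc_cv_filter(pt: PeakTable, cv_max: float = 30.0,
                 ) -> tuple[PeakTable, pd.Series, dict]:
    """Drop features whose QC coefficient of variation exceeds ``cv_max``%.

    CV is computed on the post-correction, pre-log scale over QC
    injections; a QC mean of zero makes the CV undefined and drops the
    feature.  The summary reports the median and IQR of CVs across
    retained features.
    """
    qc = pt.rows_of("qc")
    if len(qc) < 2:
        raise PeakTableError("CV filter needs >= 2 QC injections")
    block = pt.abundance.loc[qc]
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    cv = pd.Series(np.where(mean > 0, 100.0 * sd / mean, np.nan),
                   index=pt.features)
    dropped = cv.index[(cv.isna()) | (cv > cv_max)]
    kept = [f for f in pt.features if f not in set(dropped)]
    summary = {}
    if kept:
        q1, med, q3 = np.percentile(cv[kept].to_numpy(float), [25, 50, 75])
        summary = {"median_cv": float(med), "iqr_low": float(q1),
                   "iqr_high": float(q3)}
    logger.info("qc_cv_filter: dropped %d of %d features (CV > %.3g%%)",
                len(dropped), len(pt.features), cv_max)
    return pt.replace(abundance=pt.abundance[kept]), cv, summary


# --------------------------------------------------------------------------
# 7. log z-scores over study samples
# --------------------------------------------------------------------------

def to_zscores(pt: PeakTable) -> tuple[pd.DataFrame, pd.Series]:
    """Log-transform and standardize each metabolite over study samples.

    z = (log x − mean log x) / SD(log x) with the sample SD (ddof = 1),
    computed over study injections only; QC and blank rows are excluded
    from the output.  Zero-variance features cannot be standardized and
    are dropped with a fate record.
    """
    study = pt.rows_of("study")
    block = pt.abundance.loc[study]
    if (block.to_numpy(float) <= 0).any() or block.isna().to_numpy().any():
        raise PeakTableError("z-scoring requires complete positive abundances")
    logs = np.log(block)
    sd = logs.std(axis=0, ddof=1)
    dead = sd.index[sd == 0]
    fates = pd.Series(FATE_ZERO_VARIANCE, index=dead, dtype=object)
    kept = [f for f in pt.features if f not in set(dead)]
    z = (logs[kept] - logs[kept].mean(axis=0)) / sd[kept]
    return z, fates


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_preprocess(pt: PeakTable, cfg: RunConfig | None = None,
                   ) -> NormalizedMatrix:
    """Run the full chain and assemble the per-feature QC report."""
    cfg = cfg or RunConfig()
    all_features = pt.features
    report = pd.DataFrame(index=all_features,
                          columns=["fate", "chosen_is", "r2", "cv",
                                   "n_imputed"], dtype=object)

    pt1, fates1 = filter_features(pt, cfg.prevalence_min, cfg.blank_ratio_max)
    report.loc[fates1.index, "fate"] = fates1

    assign, _r2 = assign_internal_standards(pt1, cfg.r2_min)
    report.loc[assign.index, "r2"] = assign["r2"]
    omitted = assign.index[assign["chosen_is"] == "omitted"]
    for f in omitted:
        report.loc[f, "fate"] = (FATE_ALL_BELOW_LOD_QC
                                 if assign.loc[f, "note"] == "all_below_lod_qc"
                                 else FATE_R2)
    report.loc[assign.index[assign["chosen_is"] != "omitted"], "chosen_is"] = \
        assign.loc[assign["chosen_is"] != "omitted", "chosen_is"]

    pt2, _lost = normalize_by_is(pt1, assign)
    pt3, factors = median_center_batches(pt2)
    pt4, n_imp, fates4 = impute_half_min(pt3)
    report.loc[fates4.index, "fate"] = fates4
    report.loc[n_imp.index, "n_imputed"] = n_imp

    pt5, cv, cv_summary = qc_cv_filter(pt4, cfg.cv_max)
    report.loc[cv.index, "cv"] = cv
    cv_dropped = [f for f in pt4.features if f not in set(pt5.features)]
    report.loc[cv_dropped, "fate"] = FATE_CV

    z, fates7 = to_zscores(pt5)
    report.loc[fates7.index, "fate"] = fates7
    report.loc[z.columns, "fate"] = FATE_RETAINED

    logger.info("preprocess: retained %d of %d features",
                z.shape[1], len(all_features))
    return NormalizedMatrix(z=z, feature_report=report,
                            batch_factors=factors.loc[
                                [f for f in factors.index if f in set(z.columns)]],
                            qc_cv_summary=cv_summary)
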