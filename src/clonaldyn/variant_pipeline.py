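"""Downstream statistics for longitudinal somatic-variant call sets.

The experimental design this serves: a seed culture is expanded under two
serum conditions (slow 1% FBS vs fast 5% FBS), sampled in replicate at two
time points, and whole-genome sequenced with the seed culture as the
baseline for calling newly acquired variants.  Upstream read processing and
variant calling are out of scope; the input is a merged call set (VCF v4.2
or a flat TSV) plus a sample sheet.

Exclusion filters (applied to each variant record):

* depth:   excluded if detected with 10 or fewer reads in every culture
           sample (strict at 10: depth 11 is kept);
* VAF:     excluded if the variant allele frequency is below 0.1 in all
           culture samples;
* baseline (strict mode):  excluded if found in more than 1% of the reads of
           the seeding sample;
* baseline (relaxed mode): the seed criterion is replaced entirely — records
           are kept up to a seed VAF of 0.1, so subclonal baseline variants
           that later rise in frequency are not discarded.

Downstream: per-sample novel-SNV counts, a two-factor fixed-effects ANOVA
(serum group x time point, interaction when estimable), a chromosome-wise
version restricted to chromosomes with at least 4 detected variants, and
VAF-distribution summaries with a rank-based two-sample comparison.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "SampleSheet",
    "FilterConfig",
    "AnovaResult",
    "read_sample_sheet",
    "read_variants",
    "filter_variants",
    "count_novel_snvs",
    "group_anova",
    "chromosomewise_analysis",
    "vaf_distribution_summary",
]


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with per-sample depth and VAF.

    ``depth`` / ``vaf`` map sample_id to read depth and allele frequency;
    ``seed_vaf`` is the fraction of reads supporting the variant in the
    seeding (baseline) sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: dict[str, int]
    vaf: dict[str, float]
    seed_vaf: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for s, v in self.vaf.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.chrom}:{self.pos} sample {s}: VAF {v} outside [0, 1]")
        for s, d in self.depth.items():
            if d < 0:
                raise ValueError(f"{self.chrom}:{self.pos} sample {s}: negative depth {d}")
        if not (0.0 <= self.seed_vaf <= 1.0):
            raise ValueError(f"seed_vaf {self.seed_vaf} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: serum group, time point, replicate, role.

    Exactly one sample has role 'seed'; (group, timepoint, replicate) is
    unique among culture samples."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "fbs_group", "timepoint", "replicate", "role")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s) {missing}")
        seeds = df[df.role == "seed"]
        if len(seeds) != 1:
            raise ValueError(f"sample sheet must name exactly one seed sample, found {len(seeds)}")
        cultures = df[df.role == "culture"]
        dup = cultures.duplicated(subset=["fbs_group", "timepoint", "replicate"])
        if dup.any():
            raise ValueError("duplicate (fbs_group, timepoint, replicate) in sample sheet")
        if df.sample_id.duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")

    @property
    def seed_sample(self) -> str:
        return str(self.frame.loc[self.frame.role == "seed", "sample_id"].iloc[0])

    @property
    def culture_samples(self) -> list[str]:
        return list(self.frame.loc[self.frame.role == "culture", "sample_id"])

    def lookup(self, sample_id: str) -> pd.Series:
        rows = self.frame[self.frame.sample_id == sample_id]
        if rows.empty:
            raise KeyError(f"sample {sample_id!r} not in sample sheet")
        return rows.iloc[0]


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion thresholds.  ``mode`` is 'strict' (seed fraction must not
    exceed 1%) or 'relaxed' (seed VAF up to 0.1 allowed)."""

    min_reads_exclusive: int = 10
    min_vaf: float = 0.1
    seed_max_fraction: float = 0.01
    relaxed_seed_vaf_max: float = 0.1
    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise ValueError(f"mode must be 'strict' or 'relaxed', got {self.mode!r}")
        if not (0 <= self.seed_max_fraction <= self.relaxed_seed_vaf_max <= 1):
            raise ValueError("need 0 <= seed_max_fraction <= relaxed_seed_vaf_max <= 1")
        if not (0 <= self.min_vaf <= 1):
            raise ValueError("min_vaf must be in [0, 1]")
        if self.min_reads_exclusive < 0:
            raise ValueError("min_reads_exclusive must be >= 0")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype={"fbs_group": str, "timepoint": str}))


def _vaf_from_ad(ad) -> float | None:
    if ad is None:
        return None
    ad = [a for a in ad if a is not None]
    if len(ad) < 2:
        return None
    total = sum(ad)
    return ad[1] / total if total > 0 else 0.0


def _read_vcf(path: str, sheet: SampleSheet) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    known = set(sheet.frame.sample_id)
    with pysam.VariantFile(path) as vf:
        vcf_samples = list(vf.header.samples)
        unknown = [s for s in vcf_samples if s not in known]
        if unknown:
            raise ValueError(f"VCF sample(s) not in sample sheet: {unknown}")
        for rec in vf:
            depth: dict[str, int] = {}
            vaf: dict[str, float] = {}
            for s in vcf_samples:
                fmt = rec.samples[s]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                af = fmt.get("AF")
                if af is not None and not np.isscalar(af):
                    af = af[0]
                ad_vaf = _vaf_from_ad(ad)
                if af is None and ad_vaf is None:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos} sample {s}: neither AF nor AD present"
                    )
                v = float(af) if af is not None else float(ad_vaf)
                if af is not None and ad_vaf is not None and abs(v - ad_vaf) > 0.01:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos} sample {s}: AF {v:.3f} disagrees "
                        f"with AD-derived VAF {ad_vaf:.3f}"
                    )
                if dp is None:
                    if ad is None:
                        raise ValueError(
                            f"{rec.chrom}:{rec.pos} sample {s}: no DP and no AD"
                        )
                    dp = int(sum(a for a in ad if a is not None))
                depth[s] = int(dp)
                vaf[s] = v
            seed = sheet.seed_sample
            records.append(
                VariantRecord(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(rec.alts[0]) if rec.alts else ".",
                    depth=depth,
                    vaf=vaf,
                    seed_vaf=vaf.get(seed, 0.0),
                )
            )
    return records


def _read_tsv(path, sheet: SampleSheet) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "sample_id", "depth", "vaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing column(s) {sorted(missing)}")
    known = set(sheet.frame.sample_id)
    unknown = set(df.sample_id) - known
    if unknown:
        raise ValueError(f"variant TSV sample(s) not in sample sheet: {sorted(unknown)}")
    seed = sheet.seed_sample
    records = []
    for key, sub in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        depth = dict(zip(sub.sample_id, sub.depth.astype(int)))
        vaf = dict(zip(sub.sample_id, sub.vaf.astype(float)))
        records.append(
            VariantRecord(
                chrom=str(key[0]),
                pos=int(key[1]),
                ref=str(key[2]),
                alt=str(key[3]),
                depth=depth,
                vaf=vaf,
                seed_vaf=float(vaf.get(seed, 0.0)),
            )
        )
    return records


def read_variants(path, sheet: SampleSheet) -> list[VariantRecord]:
    """Read a VCF (v4.2, per-sample DP plus AF and/or AD) or a flat TSV
    (columns chrom, pos, ref, alt, sample_id, depth, vaf) into validated
    records joined against the sample sheet.  Samples absent from the sheet
    are rejected; VAFs derived from AD are cross-checked against AF when
    both are present (mismatch beyond 0.01 raises)."""
    name = os.fspath(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(name, sheet)
    return _read_tsv(name, sheet)


def _excluded(rec: VariantRecord, cfg: FilterConfig, cultures: list[str]) -> bool:
    depths = [rec.depth.get(s, 0) for s in cultures]
    vafs = [rec.vaf.get(s, 0.0) for s in cultures]
    if max(depths, default=0) <= cfg.min_reads_exclusive:
        return True
    if all(v < cfg.min_vaf for v in vafs):
        return True
    if cfg.mode == "strict":
        return rec.seed_vaf > cfg.seed_max_fraction
    return rec.seed_vaf > cfg.relaxed_seed_vaf_max


def filter_variants(
    records: list[VariantRecord],
    cfg: FilterConfig,
    sheet: SampleSheet | None = None,
) -> list[VariantRecord]:
    """Apply the exclusion filters; idempotent (filtering a filtered set is a
    no-op).  When a sheet is given, only culture samples enter the depth/VAF
    criteria; otherwise every per-sample entry is treated as a culture."""
    if sheet is not None:
        cultures = sheet.culture_samples
    else:
        cultures = sorted({s for r in records for s in r.vaf})
    return [r for r in records if not _excluded(r, cfg, cultures)]


def count_novel_snvs(
    records: list[VariantRecord],
    sheet: SampleSheet,
    min_vaf: float = 0.1,
) -> pd.DataFrame:
    """Per-sample novel-SNV counts: a variant counts for a sample iff its VAF
    there reaches ``min_vaf``.  Returns one row per culture sample with its
    design coordinates (zero counts included)."""
    rows = []
    for sid in sheet.culture_samples:
        meta = sheet.lookup(sid)
        n = sum(1 for r in records if r.vaf.get(sid, 0.0) >= min_vaf)
        rows.append(
            {
                "sample_id": sid,
                "fbs_group": meta.fbs_group,
                "timepoint": meta.timepoint,
                "replicate": meta.replicate,
                "count": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    """Two-factor fixed-effects decomposition.

    Sums of squares satisfy ss_total = ss_group + ss_timepoint +
    ss_interaction + ss_within (ss_interaction is 0 when not estimable)."""

    ss_group: float
    ss_timepoint: float
    ss_interaction: float
    ss_within: float
    f_group: float
    p_group: float
    f_timepoint: float
    p_timepoint: float
    f_interaction: float
    p_interaction: float

    @property
    def ss_total(self) -> float:
        return self.ss_group + self.ss_timepoint + self.ss_interaction + self.ss_within


def group_anova(
    table: pd.DataFrame,
    response: str = "count",
    factors: tuple[str, str] = ("fbs_group", "timepoint"),
) -> AnovaResult:
    """Two-way fixed-effects ANOVA of ``response`` on the two design factors
    (type-II sums of squares via OLS; interaction included when every design
    cell has at least 2 observations).  Degenerate designs (an empty cell)
    raise with the cell named."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    for col in (response, fa, fb):
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
    cells = table.groupby([fa, fb], observed=True).size()
    levels_a = table[fa].nunique()
    levels_b = table[fb].nunique()
    if len(cells) < levels_a * levels_b:
        present = set(cells.index)
        all_cells = {
            (a, b) for a in table[fa].unique() for b in table[fb].unique()
        }
        missing = sorted(all_cells - present)
        raise ValueError(f"degenerate design: empty cell(s) {missing}")
    if (cells < 2).any() and len(table) <= levels_a * levels_b:
        raise ValueError("need >= 2 observations in at least one design cell")

    y = table[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        # no variation at all: every effect is exactly zero
        return AnovaResult(0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0)

    with_interaction = (cells >= 2).all()
    data = table.rename(columns={response: "_y", fa: "_a", fb: "_b"})
    formula = "_y ~ C(_a) * C(_b)" if with_interaction else "_y ~ C(_a) + C(_b)"
    model = smf.ols(formula, data=data).fit()
    tab = sm.stats.anova_lm(model, typ=2)

    def row(name):
        return tab.loc[name] if name in tab.index else None

    ga, gb = row("C(_a)"), row("C(_b)")
    gi = row("C(_a):C(_b)")
    res = tab.loc["Residual"]

    def fval(r):
        return float(r["F"]) if r is not None and np.isfinite(r["F"]) else 0.0

    def pval(r):
        if r is None:
            return 1.0
        p = float(r["PR(>F)"])
        return p if np.isfinite(p) else 1.0

    return AnovaResult(
        ss_group=float(ga["sum_sq"]),
        ss_timepoint=float(gb["sum_sq"]),
        ss_interaction=float(gi["sum_sq"]) if gi is not None else 0.0,
        ss_within=float(res["sum_sq"]),
        f_group=fval(ga),
        p_group=pval(ga),
        f_timepoint=fval(gb),
        p_timepoint=pval(gb),
        f_interaction=fval(gi),
        p_interaction=pval(gi),
    )


def chromosomewise_analysis(
    records: list[VariantRecord],
    sheet: SampleSheet,
    cfg: FilterConfig | None = None,
    min_variants: int = 4,
    min_vaf: float = 0.1,
) -> pd.DataFrame:
    """Per-chromosome two-way ANOVA of novel-SNV counts.

    Chromosomes with fewer than ``min_variants`` variants detected across all
    samples are excluded (boundary: exactly 4 is included).  Records are
    filtered first when a config is supplied (relaxed mode is the intended
    use).  Returns one row per retained chromosome with SS components and the
    group test; an empty frame when nothing qualifies."""
    if cfg is not None:
        records = filter_variants(records, cfg, sheet)
    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        if len(recs) < min_variants:
            continue
        counts = count_novel_snvs(recs, sheet, min_vaf=min_vaf)
        try:
            res = group_anova(counts)
        except ValueError:
            continue
        rows.append(
            {
                "chrom": chrom,
                "n_variants": len(recs),
                "ss_group": res.ss_group,
                "ss_timepoint": res.ss_timepoint,
                "ss_interaction": res.ss_interaction,
                "ss_within": res.ss_within,
                "f_group": res.f_group,
                "p_group": res.p_group,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "n_variants", "ss_group", "ss_timepoint",
            "ss_interaction", "ss_within", "f_group", "p_group",
        ],
    )


def _mode_location(values: np.ndarray) -> float:
    """KDE argmax on [0, 1]; falls back to the mean for degenerate samples."""
    if values.size < 3 or np.allclose(values, values[0]):
        return float(values.mean()) if values.size else math.nan
    kde = stats.gaussian_kde(values)
    grid = np.linspace(0.0, 1.0, 501)
    return float(grid[int(np.argmax(kde(grid)))])


def vaf_distribution_summary(
    records: list[VariantRecord],
    sheet: SampleSheet,
    min_vaf: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """VAF-distribution summaries per (group, timepoint) and a rank-based
    two-sample comparison between the serum groups (two-sided Mann-Whitney
    on pooled per-detection VAFs).  Returns (summary frame, p-value)."""
    pooled: dict[str, list[float]] = {}
    per_cell: dict[tuple[str, str], list[float]] = {}
    for sid in sheet.culture_samples:
        meta = sheet.lookup(sid)
        for r in records:
            v = r.vaf.get(sid, 0.0)
            if v >= min_vaf:
                pooled.setdefault(str(meta.fbs_group), []).append(v)
                per_cell.setdefault((str(meta.fbs_group), str(meta.timepoint)), []).append(v)
    rows = []
    for (g, tp), vals in sorted(per_cell.items()):
        arr = np.asarray(vals)
        rows.append(
            {
                "fbs_group": g,
                "timepoint": tp,
                "n": arr.size,
                "mean_vaf": float(arr.mean()),
                "mode_vaf": _mode_location(arr),
                "sd_vaf": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(
        rows, columns=["fbs_group", "timepoint", "n", "mean_vaf", "mode_vaf", "sd_vaf"]
    )
    groups = sorted(pooled)
    if len(groups) == 2 and all(len(pooled[g]) > 0 for g in groups):
        a, b = (np.asarray(pooled[g]) for g in groups)
        if np.array_equal(a, b):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        p = math.nan
    return summary, p
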