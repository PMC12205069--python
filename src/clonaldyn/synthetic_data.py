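"""Seeded generators for every input the pipeline consumes.

Nothing here downloads anything: the generators emulate the *statistical
structure* of the real inputs — a COSMIC-style scored mutation catalog, PDX /
cell-line growth curves, and longitudinal WGS variant tables — so that every
stage of the pipeline is testable offline, with a machine-readable truth
sidecar for exact recovery tests.

Conventions:

* every generator takes an integer ``seed`` and is byte-deterministic for a
  fixed seed (NumPy PCG64 stream, fixed text formatting);
* every generated file parses cleanly through the corresponding reader;
* planted truth (true growth rate per series, true counts per sample, true
  filter verdict per variant) is returned alongside the data and written as
  ``truth.json`` next to any file output.

Default parameter choices mirror the study conditions the pipeline analyses:
growth cohorts with fast pediatric-like rates (median ~10 and ~31 on
normalized time) and slow adult-like rates (~0.7-1), a quarter of series
non-logistic; variant tables with per-sample novel-SNV counts around 6 at
week 3 rising to 7 (slow) vs 20 (fast) at week 6, unimodal VAFs near 0.25,
sequencing depths around 30x, and a seed-culture baseline carrying subclonal
contamination on both sides of the 1% and 10% thresholds.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth_fit import GrowthSeries
from .mutation_catalog import MutationCatalog, ScoredMutation
from .variant_pipeline import SampleSheet, VariantRecord

__all__ = [
    "gen_catalog",
    "CohortSpec",
    "default_cohorts",
    "gen_growth",
    "VariantDesign",
    "gen_variants",
    "gen_count_table",
    "write_catalog_tsv",
    "write_growth_csv",
    "write_variants_tsv",
    "write_variants_vcf",
]


# ---------------------------------------------------------------- catalog

def gen_catalog(
    n_neutral: int = 1000,
    n_driver: int = 50,
    n_strong: int = 10,
    seed: int = 0,
    out_path=None,
) -> MutationCatalog:
    """Synthetic scored catalog with exact class counts.

    Scores are uniform within each class band: neutral on (0, 0.5], driver on
    (0.5, 0.7], strong driver on (0.7, 1), so classification reproduces the
    requested partition sizes exactly.
    """
    if min(n_neutral, n_driver, n_strong) < 0:
        raise ValueError("partition counts must be >= 0")
    rng = np.random.default_rng(seed)
    entries: list[ScoredMutation] = []
    # (1 - u) maps U[0,1) onto (0,1], keeping the class-band edges half-open
    for i in range(n_neutral):
        entries.append(ScoredMutation(f"NEU{i:05d}", round(0.5 * (1 - rng.random()), 6)))
    for i in range(n_driver):
        entries.append(
            ScoredMutation(f"DRV{i:05d}", round(0.5 + 0.2 * (1 - rng.random()), 6))
        )
    for i in range(n_strong):
        entries.append(
            ScoredMutation(f"STR{i:05d}", round(min(0.7 + 0.3 * (1 - rng.random()), 0.999999), 6))
        )
    cat = MutationCatalog(entries=entries)
    if out_path is not None:
        write_catalog_tsv(cat, out_path)
    return cat


def write_catalog_tsv(cat: MutationCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mutation_id\tscore\n")
        for e in cat.entries:
            fh.write(f"{e.mutation_id}\t{e.score:.6f}\n")


# ----------------------------------------------------------------- growth

@dataclass(frozen=True)
class CohortSpec:
    """One synthetic cohort of growth series.

    ``r_median``/``r_sigma`` parameterize a log-normal over true growth
    rates (normalized-time units); ``contaminant_fraction`` of series are
    non-logistic (an abrupt collapse-and-recovery measurement artifact).
    """

    name: str
    n_series: int = 10
    r_median: float = 10.0
    r_sigma: float = 0.35
    capacity_range: tuple[float, float] = (1500.0, 5000.0)
    n0_frac_range: tuple[float, float] = (0.02, 0.1)
    n_points: int = 8
    noise_sd: float = 0.05
    contaminant_fraction: float = 0.0
    value_kind: str = "volume"


def default_cohorts() -> list[CohortSpec]:
    """Cohorts emulating the study's model systems: fast pediatric xenografts
    (medians ~10 and ~31), slow adult cell-line xenografts (~0.7 and ~0.9),
    with a quarter of series failing to grow logistically."""
    common = dict(n_series=12, n_points=8, noise_sd=0.05, contaminant_fraction=0.25)
    return [
        CohortSpec(name="NB", r_median=10.0, **common),
        CohortSpec(name="WT", r_median=31.0, **common),
        CohortSpec(name="lung", r_median=0.68, **common),
        CohortSpec(name="breast", r_median=0.9, **common),
    ]


def _logistic_curve(t, n0, c, r):
    return c * n0 / (n0 + (c - n0) * np.exp(-r * t))


def gen_growth(
    cohorts: list[CohortSpec] | None = None,
    seed: int = 0,
    out_csv=None,
) -> tuple[list[GrowthSeries], dict]:
    """Synthetic growth series with a planted-truth sidecar.

    Logistic series are evaluated from the closed-form solution on
    normalized time with multiplicative log-normal measurement noise;
    contaminants are non-monotone artifact series (an abrupt mid-series
    collapse and recovery) that no logistic curve fits well.  Returns (series list, truth dict); with
    ``out_csv`` also writes the CSV and a truth.json next to it.
    """
    if cohorts is None:
        cohorts = default_cohorts()
    rng = np.random.default_rng(seed)
    series: list[GrowthSeries] = []
    truth: dict = {"seed": seed, "rng": "numpy PCG64", "series": {}}
    for spec in cohorts:
        n_cont = int(round(spec.contaminant_fraction * spec.n_series))
        for i in range(spec.n_series):
            sid = f"{spec.name}_{i:03d}"
            t = np.linspace(0.0, 1.0, spec.n_points)
            c = rng.uniform(*spec.capacity_range)
            n0 = c * rng.uniform(*spec.n0_frac_range)
            contaminant = i < n_cont
            if contaminant:
                # measurement artifact: a logistic course with an abrupt
                # mid-series collapse-and-recovery; non-monotone, so no
                # logistic curve explains it well
                r_art = float(spec.r_median * np.exp(rng.normal(0.0, spec.r_sigma)))
                v = _logistic_curve(t, n0, c, max(r_art, 3.0))
                dip_at = int(rng.integers(2, spec.n_points - 2))
                v = v.copy()
                v[dip_at : dip_at + 2] *= 0.2
                r_true = None
            else:
                r_true = float(spec.r_median * np.exp(rng.normal(0.0, spec.r_sigma)))
                v = _logistic_curve(t, n0, c, r_true)
            if spec.noise_sd > 0:
                v = v * np.exp(rng.normal(0.0, spec.noise_sd, size=v.size))
            series.append(
                GrowthSeries(
                    series_id=sid,
                    group=spec.name,
                    times=t,
                    values=np.round(v, 4),
                    value_kind=spec.value_kind,
                )
            )
            truth["series"][sid] = {
                "group": spec.name,
                "r_true": r_true,
                "capacity": round(float(c), 4),
                "n0": round(float(n0), 4),
                "contaminant": bool(contaminant),
            }
    if out_csv is not None:
        write_growth_csv(series, out_csv)
        _write_truth(out_csv, truth)
    return series, truth


def write_growth_csv(series: list[GrowthSeries], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("series_id,group,time,value,value_kind\n")
        for s in series:
            for t, v in zip(s.times, s.values):
                fh.write(f"{s.series_id},{s.group},{t:.6f},{v:.4f},{s.value_kind}\n")


# --------------------------------------------------------------- variants

@dataclass(frozen=True)
class VariantDesign:
    """Design of a synthetic longitudinal variant call set.

    ``count_means`` maps (fbs_group, timepoint) to the expected number of
    novel SNVs per culture sample (Poisson).  VAFs of planted novel variants
    are Beta(vaf_a, vaf_b) truncated at ``min_vaf`` (they are detected
    variants by construction); depths are 11 + NegBin (so the depth filter
    only fires on explicitly planted low-depth variants).
    """

    groups: tuple[str, ...] = ("1%", "5%")
    timepoints: tuple[str, ...] = ("week3", "week6")
    replicates: int = 3
    count_means: dict = field(
        default_factory=lambda: {
            ("1%", "week3"): 6.0,
            ("5%", "week3"): 6.0,
            ("1%", "week6"): 7.0,
            ("5%", "week6"): 20.0,
        }
    )
    vaf_a: float = 2.5
    vaf_b: float = 7.5  # mean a/(a+b) = 0.25
    min_vaf: float = 0.1
    depth_nb_n: float = 10.0
    depth_nb_p: float = 0.34  # 11 + NB mean ~19.4 -> ~30x overall
    n_seed_low: int = 4  # seed VAF in (0.01, 0.1]: strict drops, relaxed keeps
    n_seed_high: int = 3  # seed VAF > 0.1: both modes drop
    n_low_depth: int = 3  # planted depth <= 10 everywhere: depth filter
    n_chromosomes: int = 8
    sparse_chromosomes: int = 2  # chromosomes forced under the >=4-variant rule


def _beta_truncated(rng, a, b, low, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=size)
        keep = draw[draw >= low]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def gen_variants(
    design: VariantDesign | None = None,
    seed: int = 0,
    out_dir=None,
) -> tuple[list[VariantRecord], SampleSheet, dict]:
    """Synthetic variant call set + sample sheet + truth sidecar.

    Per culture sample, a Poisson number of novel variants is planted with
    truncated-Beta VAFs (unimodal around 0.25) and ~30x depths; additional
    variants exercise each exclusion branch: seed contamination in the
    (1%, 10%] band (kept only in relaxed mode), above 10% (always dropped),
    and low-depth variants (always dropped).  Chromosome labels are assigned
    so the chromosome-wise >=4-variant rule has both passing and failing
    chromosomes.  With ``out_dir``, writes variants.tsv, variants.vcf,
    sheet.csv and truth.json.
    """
    if design is None:
        design = VariantDesign()
    rng = np.random.default_rng(seed)

    sheet_rows = [
        {"sample_id": "S1", "fbs_group": "none", "timepoint": "baseline",
         "replicate": 0, "role": "seed"}
    ]
    idx = 2
    for g in design.groups:
        for tp in design.timepoints:
            for rep in range(1, design.replicates + 1):
                sheet_rows.append(
                    {"sample_id": f"S{idx}", "fbs_group": g, "timepoint": tp,
                     "replicate": rep, "role": "culture"}
                )
                idx += 1
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    cultures = sheet.culture_samples
    seed_sample = sheet.seed_sample

    # chromosome labels: the first `sparse_chromosomes` get at most 3
    # variants; the rest share the bulk
    dense = [f"chr{i}" for i in range(design.sparse_chromosomes + 1,
                                      design.n_chromosomes + 1)]
    sparse = [f"chr{i}" for i in range(1, design.sparse_chromosomes + 1)]
    sparse_budget = {c: 3 for c in sparse}

    records: list[VariantRecord] = []
    truth_variants: dict = {}
    true_counts = {}
    pos_counter = {c: 0 for c in dense + sparse}
    bases = np.array(list("ACGT"))

    def new_site(chrom):
        pos_counter[chrom] += 1
        pos = 10_000 * pos_counter[chrom] + int(rng.integers(1, 9999))
        ref, alt = rng.choice(bases, size=2, replace=False)
        return pos, str(ref), str(alt)

    def depth_draw():
        return 11 + int(rng.negative_binomial(design.depth_nb_n, design.depth_nb_p))

    def pick_chrom():
        # occasionally place a variant on a sparse chromosome while its
        # budget lasts, so the >=4 rule has genuinely failing chromosomes
        open_sparse = [c for c in sparse if sparse_budget[c] > 0]
        if open_sparse and rng.random() < 0.08:
            c = open_sparse[int(rng.integers(len(open_sparse)))]
            sparse_budget[c] -= 1
            return c
        return dense[int(rng.integers(len(dense)))]

    def make_record(chrom, present: dict[str, float], seed_vaf: float,
                    seed_band: tuple[float, float] | None = None):
        # VAFs are quantized to whole read counts (alt/depth) so that flat
        # TSV, VCF AF, and AD-derived frequencies all agree exactly;
        # detected VAFs stay >= min_vaf and seed VAFs stay inside their
        # intended filter band after quantization
        pos, ref, alt = new_site(chrom)
        depth = {s: depth_draw() for s in cultures}
        vaf = {}
        for s in cultures:
            v = float(present.get(s, 0.0))
            if v > 0:
                dp = depth[s]
                reads = int(np.clip(round(dp * v), math.ceil(design.min_vaf * dp), dp))
                v = reads / dp
            vaf[s] = round(v, 6)
        sdp = depth_draw()
        depth[seed_sample] = sdp
        if seed_vaf > 0 and seed_band is not None:
            lo = int(math.floor(seed_band[0] * sdp)) + 1
            hi = max(int(math.floor(seed_band[1] * sdp)), lo)
            reads = int(np.clip(round(sdp * seed_vaf), lo, hi))
            seed_vaf = reads / sdp
        vaf[seed_sample] = round(float(seed_vaf), 6)
        return VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                             depth=depth, vaf=vaf, seed_vaf=vaf[seed_sample])

    # planted novel variants per culture sample
    for sid in cultures:
        meta = sheet.lookup(sid)
        mean = design.count_means[(str(meta.fbs_group), str(meta.timepoint))]
        k = int(rng.poisson(mean))
        true_counts[sid] = k
        vafs = _beta_truncated(rng, design.vaf_a, design.vaf_b, design.min_vaf, k)
        for v in vafs:
            rec = make_record(pick_chrom(), {sid: float(round(v, 4))}, 0.0)
            records.append(rec)
            truth_variants[f"{rec.chrom}:{rec.pos}"] = {
                "kind": "novel", "sample": sid,
                "strict_kept": True, "relaxed_kept": True,
            }

    # seed-contaminated variants: visible in several cultures
    for i in range(design.n_seed_low):
        sv = float(round(rng.uniform(0.011, 0.1), 4))
        present = {s: float(round(v, 4))
                   for s, v in zip(cultures, _beta_truncated(
                       rng, design.vaf_a, design.vaf_b, design.min_vaf, len(cultures)))}
        rec = make_record(pick_chrom(), present, sv, seed_band=(0.01, 0.1))
        records.append(rec)
        truth_variants[f"{rec.chrom}:{rec.pos}"] = {
            "kind": "seed_low", "strict_kept": False, "relaxed_kept": True,
        }
    for i in range(design.n_seed_high):
        sv = float(round(rng.uniform(0.101, 0.4), 4))
        present = {s: float(round(v, 4))
                   for s, v in zip(cultures, _beta_truncated(
                       rng, design.vaf_a, design.vaf_b, design.min_vaf, len(cultures)))}
        rec = make_record(pick_chrom(), present, sv, seed_band=(0.1, 0.5))
        records.append(rec)
        truth_variants[f"{rec.chrom}:{rec.pos}"] = {
            "kind": "seed_high", "strict_kept": False, "relaxed_kept": False,
        }

    # low-depth variants (depth <= 10 in every culture sample)
    for i in range(design.n_low_depth):
        chrom = pick_chrom()
        pos, ref, alt = new_site(chrom)
        depth = {s: int(rng.integers(3, 11)) for s in cultures}
        vaf = {
            s: round(max(1, int(round(depth[s] * rng.uniform(0.15, 0.4)))) / depth[s], 6)
            for s in cultures
        }
        depth[seed_sample] = depth_draw()
        vaf[seed_sample] = 0.0
        rec = VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                            depth=depth, vaf=vaf, seed_vaf=0.0)
        records.append(rec)
        truth_variants[f"{rec.chrom}:{rec.pos}"] = {
            "kind": "low_depth", "strict_kept": False, "relaxed_kept": False,
        }

    truth = {
        "seed": seed,
        "rng": "numpy PCG64",
        "true_counts": true_counts,
        "variants": truth_variants,
        "note": "synthetic stand-in for a longitudinal WGS call set",
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_variants_tsv(records, os.path.join(out_dir, "variants.tsv"))
        write_variants_vcf(records, sheet, os.path.join(out_dir, "variants.vcf"))
        sheet.frame.to_csv(os.path.join(out_dir, "sheet.csv"), index=False)
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return records, sheet, truth


def write_variants_tsv(records: list[VariantRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\tsample_id\tdepth\tvaf\n")
        for r in sorted(records, key=lambda x: x.key):
            for s in sorted(r.vaf):
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{s}\t{r.depth[s]}\t{r.vaf[s]:.6f}\n"
                )


def write_variants_vcf(records: list[VariantRecord], sheet: SampleSheet, path) -> None:
    """Minimal VCF v4.2 with per-sample DP, AD and AF (AD consistent with
    AF and DP by construction)."""
    samples = list(sheet.frame.sample_id)
    chroms = sorted({r.chrom for r in records})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonaldyn-synthetic\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for r in sorted(records, key=lambda x: x.key):
            cols = [r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS", ".", "DP:AD:AF"]
            for s in samples:
                dp = r.depth.get(s, 0)
                af = r.vaf.get(s, 0.0)
                alt_reads = int(round(dp * af))
                cols.append(f"{dp}:{dp - alt_reads},{alt_reads}:{af:.6f}")
            fh.write("\t".join(cols) + "\n")


def _write_truth(data_path, truth: dict) -> None:
    base = os.fspath(data_path)
    root, _ = os.path.splitext(base)
    with open(root + ".truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


# ------------------------------------------------------------ count table

def gen_count_table(
    means: dict[tuple[str, str], float],
    variances: dict[tuple[str, str], float],
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-sample count table with normal noise at specified per-cell
    means and variances — the shape expected by :func:`group_anova`."""
    rng = np.random.default_rng(seed)
    rows = []
    for (g, tp), mu in means.items():
        sd = float(np.sqrt(variances[(g, tp)]))
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{g}-{tp}-r{rep}",
                    "fbs_group": g,
                    "timepoint": tp,
                    "replicate": rep,
                    "count": float(rng.normal(mu, sd)),
                }
            )
    return pd.DataFrame(rows)
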