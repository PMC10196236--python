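"""End-to-end orchestration at desk scale.

Annotates every missense mutation against the reference pentamer frequency
tables and the per-allele binding predictors, producing one record per
(mutation x width x binding register) with wildtype and mutant TCEM, their
reference counts, within-protein Zscale binding scores for every genotype
slot, genotype bitmaps, and down-selection summaries per case.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import io as nio
from .binding_model import BindingPredictor, predict_protein
from .genotype_logic import (
    CLASS_I_SLOTS,
    CLASS_II_SLOTS,
    DEFAULT_THRESHOLD,
    DownselectTable,
    RegisterMatrix,
    bitmap_class_i,
    bitmap_class_ii,
    classify_binding_change,
    cumulative_fraction_by_ppf,
    downselect,
    exposure_fraction,
    genotype_from_row,
    pattern_diversity,
    register_matrix,
)
from .motif_core import (
    Mutation,
    MutationVerificationError,
    ProteinRecord,
    apply_mutation,
    dedupe_mutations,
    enumerate_mutant_registers,
    extract_gem_i,
    extract_gem_ii,
    extract_tcem_i,
    extract_tcem_ii,
    mutant_relative_index,
    window_peptides,
)
from .ppf_db import PentamerTable, frequency_class
from .stat_models import FitError, ZipFit, fit_shash, fit_weibull_growth, fit_zip, standardize
from .synthetic_data import gen_binding_truth


class ConfigError(ValueError):
    """A run configuration references inputs that cannot be resolved."""


@dataclass
class MutWtComparison:
    """Paired mutant-vs-wildtype frequency report over exposed TCEM records."""

    zip_wt: ZipFit
    zip_mut: ZipFit
    class_tally_wt: dict[str, int]
    class_tally_mut: dict[str, int]
    lrt_statistic: float
    lrt_p: float  # likelihood-ratio test of a common (lambda, pi); an extension
    n_records: int


@dataclass
class CaseSummary:
    case_id: str
    downselect: DownselectTable
    exposure_fraction_events: float
    exposure_fraction_peptides: float
    n_patterns: int
    entropy_bits: float
    zip_wt: Optional[ZipFit]
    zip_mut: Optional[ZipFit]
    weibull: Optional[dict]

    def as_dict(self) -> dict:
        def zipd(z):
            if z is None:
                return None
            return {"lambda": z.lambda_hat, "pi": z.pi_hat, "n": z.n,
                    "degenerate": z.degenerate}
        return {
            "case_id": self.case_id,
            "downselect": self.downselect.as_dict(),
            "exposure_fraction_events": self.exposure_fraction_events,
            "exposure_fraction_peptides": self.exposure_fraction_peptides,
            "n_patterns": self.n_patterns,
            "entropy_bits": self.entropy_bits,
            "zip_wt": zipd(self.zip_wt),
            "zip_mut": zipd(self.zip_mut),
            "weibull": self.weibull,
        }


def _allele_seed(allele: str, seed: int) -> int:
    return (zlib.crc32(allele.encode()) ^ (seed * 2654435761)) % (2**31 - 1)


def make_truth_predictors(
    genotypes: pd.DataFrame, seed: int, anchor_factor: float = 5.0
) -> dict[str, BindingPredictor]:
    """Noise-free synthetic truth predictor per allele in the genotype table.

    Class I alleles get a 9mer energy function, DRB1 alleles a 15mer one;
    each allele's weights are a deterministic function of (allele name, seed).
    """
    preds: dict[str, BindingPredictor] = {}
    for slot in CLASS_I_SLOTS:
        for allele in genotypes[slot].unique():
            preds.setdefault(
                allele,
                gen_binding_truth(allele, _allele_seed(allele, seed), width=9,
                                  anchor_factor=anchor_factor),
            )
    for slot in CLASS_II_SLOTS:
        for allele in genotypes[slot].unique():
            preds.setdefault(
                allele,
                gen_binding_truth(allele, _allele_seed(allele, seed), width=15,
                                  anchor_factor=anchor_factor),
            )
    return preds


class _ZscoreCache:
    """Within-protein Zscale scores per (sequence, allele), computed lazily."""

    def __init__(self, predictors: dict[str, BindingPredictor]):
        self.predictors = predictors
        self._cache: dict[tuple[str, str, bool], dict[int, float]] = {}

    def zscores(self, protein: ProteinRecord, allele: str) -> dict[int, float]:
        key = (protein.protein_id, allele, protein.is_mutant)
        if key not in self._cache:
            predictor = self.predictors.get(allele)
            if predictor is None:
                raise ConfigError(f"no binding predictor for allele {allele!r}")
            preds = predict_protein(predictor, protein, predictor.width)
            if not preds:
                self._cache[key] = {}
            else:
                windows = window_peptides(protein, predictor.width)
                vals = np.array([p.mean_ln_ic50 for p in preds])
                fit = fit_shash(vals, fitted_on="ln_ic50")
                z = standardize(vals, fit)
                self._cache[key] = {w.start: float(v) for w, v in zip(windows, z)}
        return self._cache[key]


def annotate_mutations(
    proteome: Sequence[ProteinRecord],
    mutations: Sequence[Mutation],
    ppf_i: PentamerTable,
    ppf_ii: PentamerTable,
    predictors: dict[str, BindingPredictor],
    genotypes: pd.DataFrame,
    ppf_i_micro: Optional[PentamerTable] = None,
    ppf_ii_micro: Optional[PentamerTable] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, list[dict]]:
    """One record per (mutation x width x register); exclusions reported.

    Unresolvable mutations (unknown protein, reference residue mismatch) are
    listed with a reason code and skipped, never silently dropped.
    """
    by_id = {p.protein_id: p for p in proteome}
    geno_by_case = {row["case_id"]: genotype_from_row(row) for _, row in genotypes.iterrows()}
    cache = _ZscoreCache(predictors)
    rows: list[dict] = []
    exclusions: list[dict] = []

    for mut in dedupe_mutations(list(mutations)):
        wt = by_id.get(mut.protein_id)
        if wt is None:
            exclusions.append({"case_id": mut.case_id, "protein_id": mut.protein_id,
                               "position": mut.position, "reason": "missing_protein"})
            continue
        try:
            mt = apply_mutation(wt, mut)
        except MutationVerificationError:
            exclusions.append({"case_id": mut.case_id, "protein_id": mut.protein_id,
                               "position": mut.position, "reason": "ref_mismatch"})
            continue
        genotype = geno_by_case.get(mut.case_id)
        if genotype is None:
            raise ConfigError(f"no genotype for case {mut.case_id!r}")
        alleles = genotype.alleles

        for width, slots in ((9, CLASS_I_SLOTS), (15, CLASS_II_SLOTS)):
            ppf = ppf_i if width == 9 else ppf_ii
            ppf_micro = ppf_i_micro if width == 9 else ppf_ii_micro
            z_mut = {s: cache.zscores(mt, alleles[s]) for s in slots}
            z_wt = {s: cache.zscores(wt, alleles[s]) for s in slots}
            for pa in enumerate_mutant_registers(mt, mut, width):
                start = pa.window.start
                wt_pep = wt.sequence[start - 1 : start - 1 + width]
                if width == 9:
                    tcem_wt, gem_wt = extract_tcem_i(wt_pep), extract_gem_i(wt_pep)
                else:
                    tcem_wt, gem_wt = extract_tcem_ii(wt_pep), extract_gem_ii(wt_pep)
                row = {
                    "case_id": mut.case_id,
                    "protein_id": mut.protein_id,
                    "position": mut.position,
                    "ref_aa": mut.ref_aa,
                    "alt_aa": mut.alt_aa,
                    "width": width,
                    "start": start,
                    "offset": mutant_relative_index(pa.window, mut),
                    "pocket": -1 if pa.mutant_pocket is None else pa.mutant_pocket,
                    "exposed": pa.exposed,
                    "tcem_wt": tcem_wt.pentamer,
                    "tcem_mut": pa.tcem.pentamer,
                    "gem_wt": gem_wt.tetramer,
                    "gem_mut": pa.gem.tetramer,
                    "hppf_wt": ppf.lookup(tcem_wt.pentamer),
                    "hppf_mut": ppf.lookup(pa.tcem.pentamer),
                    "gippf_wt": ppf_micro.lookup(tcem_wt.pentamer) if ppf_micro else np.nan,
                    "gippf_mut": ppf_micro.lookup(pa.tcem.pentamer) if ppf_micro else np.nan,
                }
                zs_mut, zs_wt = [], []
                for s in slots:
                    zm = z_mut[s].get(start, np.nan)
                    zw = z_wt[s].get(start, np.nan)
                    row[f"z_mut_{s}"] = zm
                    row[f"z_wt_{s}"] = zw
                    zs_mut.append(zm)
                    zs_wt.append(zw)
                if width == 9:
                    row["bitmap"] = bitmap_class_i(zs_mut, pa.exposed, threshold)
                else:
                    row["bitmap"] = bitmap_class_ii(zs_mut, pa.exposed, threshold)
                rows.append(row)
    return pd.DataFrame(rows), exclusions


def compare_mut_wt(annotations: pd.DataFrame, min_records: int = 10) -> MutWtComparison:
    """ZIP fits of wildtype vs mutant exposed-TCEM reference counts (class I).

    The likelihood-ratio test of a shared (lambda, pi) is an extension beyond
    the distributional fits themselves.
    """
    df = annotations[(annotations["width"] == 9) & annotations["exposed"].astype(bool)]
    if len(df) < min_records:
        raise ValueError(f"need >= {min_records} exposed records, got {len(df)}")
    wt = df["hppf_wt"].to_numpy(dtype=int)
    mut = df["hppf_mut"].to_numpy(dtype=int)
    zip_wt, zip_mut = fit_zip(wt), fit_zip(mut)
    pooled = fit_zip(np.concatenate([wt, mut]))
    if zip_wt.degenerate or zip_mut.degenerate or pooled.degenerate:
        lrt, p = float("nan"), float("nan")
    else:
        lrt = 2.0 * (zip_wt.loglik + zip_mut.loglik - pooled.loglik)
        p = float(sstats.chi2.sf(lrt, df=2))
    tally = lambda a: pd.Series([frequency_class(int(v)) for v in a]).value_counts().to_dict()
    return MutWtComparison(zip_wt, zip_mut, tally(wt), tally(mut), lrt, p, len(df))


def mutant_alignment_profile(annotations: pd.DataFrame, width: int = 9) -> pd.DataFrame:
    """Mean standardized log2(1+hPPF) per mutant-relative window offset.

    The pooled wildtype+mutant values are SHASH-standardized once, so the
    wildtype and mutant profiles share a scale; offsets whose TCEM excludes
    the mutant are identical between the two by construction.
    """
    df = annotations[annotations["width"] == width]
    if not len(df):
        return pd.DataFrame(columns=["offset", "mean_wt", "mean_mut", "n"])
    vals_wt = np.log2(1.0 + df["hppf_wt"].to_numpy(dtype=float))
    vals_mut = np.log2(1.0 + df["hppf_mut"].to_numpy(dtype=float))
    fit = fit_shash(np.concatenate([vals_wt, vals_mut]), fitted_on="log2(1+count)")
    z_wt = standardize(vals_wt, fit)
    z_mut = standardize(vals_mut, fit)
    tmp = pd.DataFrame({"offset": df["offset"].to_numpy(), "z_wt": z_wt, "z_mut": z_mut})
    prof = (
        tmp.groupby("offset")
        .agg(mean_wt=("z_wt", "mean"), mean_mut=("z_mut", "mean"), n=("z_wt", "size"))
        .reset_index()
        .sort_values("offset", ignore_index=True)
    )
    return prof


def binding_change_table(annotations: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Long-format Lost/Gained/Retained classes per (record, allele slot)."""
    out = []
    for width, slots in ((9, CLASS_I_SLOTS), (15, CLASS_II_SLOTS)):
        df = annotations[annotations["width"] == width]
        for s in slots:
            zw, zm = df[f"z_wt_{s}"], df[f"z_mut_{s}"]
            ok = zw.notna() & zm.notna()
            sub = df[ok]
            out.append(pd.DataFrame({
                "width": width,
                "pocket": sub["pocket"].to_numpy(),
                "slot": s,
                "change": [classify_binding_change(a, b, threshold)
                           for a, b in zip(zw[ok], zm[ok])],
            }))
    return pd.concat(out, ignore_index=True)


def register_matrices(annotations: pd.DataFrame) -> dict[tuple, RegisterMatrix]:
    """Per-mutation 6 (allele) x 5 (exposing register) minimum-Zscale matrices."""
    df9 = annotations[(annotations["width"] == 9) & annotations["exposed"].astype(bool)]
    out = {}
    for key, grp in df9.groupby(["case_id", "protein_id", "position", "alt_aa"]):
        m = np.full((6, 5), np.nan)
        for row in grp.itertuples(index=False):
            reg = int(row.pocket) - 4  # pockets 4..8 -> registers 0..4
            for i, s in enumerate(CLASS_I_SLOTS):
                m[i, reg] = getattr(row, f"z_mut_{s}")
        out[key] = register_matrix(m)
    return out


# ---------------------------------------------------------------------------
# run_case: full per-case orchestration
# ---------------------------------------------------------------------------


def _resolve(config: dict) -> dict:
    """Resolve paths/objects in a run config; fail before any compute."""
    from .ppf_db import build_ppf, load_ppf

    r = dict(config)
    try:
        if isinstance(r.get("proteome"), (str, Path)):
            r["proteome"] = nio.read_fasta(r["proteome"])
        if not r.get("proteome"):
            raise ConfigError("config must supply a proteome")
        if isinstance(r.get("microbiome"), (str, Path)):
            r["microbiome"] = nio.read_fasta(r["microbiome"])
        if isinstance(r.get("mutations"), (str, Path)):
            r["mutations"] = nio.read_mutations(r["mutations"])
        if not r.get("mutations"):
            raise ConfigError("config must supply mutations")
        if isinstance(r.get("genotypes"), (str, Path)):
            r["genotypes"] = nio.read_genotypes(r["genotypes"])
        if r.get("genotypes") is None:
            raise ConfigError("config must supply genotypes")
        for key, cls in (("ppf_i", "I"), ("ppf_ii", "II")):
            if isinstance(r.get(key), (str, Path)):
                r[key] = load_ppf(r[key])
            elif r.get(key) is None:
                r[key] = build_ppf(r["proteome"], cls, reference_name="proteome")
        for key, cls in (("ppf_i_micro", "I"), ("ppf_ii_micro", "II")):
            if isinstance(r.get(key), (str, Path)):
                r[key] = load_ppf(r[key])
            elif r.get(key) is None and r.get("microbiome"):
                r[key] = build_ppf(r["microbiome"], cls, reference_name="microbiome")
    except (OSError, ValueError) as e:
        raise ConfigError(str(e)) from e
    r.setdefault("zscale_threshold", DEFAULT_THRESHOLD)
    r.setdefault("dual_class_rule", "mutation")
    r.setdefault("ppf_cap", 10)
    r.setdefault("seed", 0)
    if r.get("predictors") is None:
        r["predictors"] = make_truth_predictors(r["genotypes"], int(r["seed"]))
    return r


def run_case(config: dict, outdir: Optional[str | Path] = None) -> tuple[list[CaseSummary], pd.DataFrame]:
    """Run the full analysis for every case in the config's genotype table.

    Writes ``annotations.tsv``, ``downselect.tsv`` and ``summary.json`` to
    ``outdir`` (or config['outdir']) when given.  Deterministic for a fixed
    config and seed.
    """
    r = _resolve(config)
    threshold = float(r["zscale_threshold"])
    ann, exclusions = annotate_mutations(
        r["proteome"], r["mutations"], r["ppf_i"], r["ppf_ii"],
        r["predictors"], r["genotypes"],
        ppf_i_micro=r.get("ppf_i_micro"), ppf_ii_micro=r.get("ppf_ii_micro"),
        threshold=threshold,
    )
    summaries: list[CaseSummary] = []
    for case_id in sorted(ann["case_id"].unique()) if len(ann) else []:
        sub = ann[ann["case_id"] == case_id]
        table = downselect(sub, threshold, r["dual_class_rule"], case_id=case_id)
        df9 = sub[sub["width"] == 9]
        n_pat, entropy = pattern_diversity(df9["bitmap"].tolist())
        try:
            comparison = compare_mut_wt(sub)
            zw, zm = comparison.zip_wt, comparison.zip_mut
        except (ValueError, FitError):
            zw = zm = None
        weibull = None
        try:
            curve = cumulative_fraction_by_ppf(sub, ppf_cap=int(r["ppf_cap"]), threshold=threshold)
            if curve["cumulative_fraction"].nunique() > 1:
                wfit = fit_weibull_growth(
                    curve["hppf"], curve["cumulative_fraction"], bound_a=1.0
                )
                weibull = {"a": wfit.a, "b": wfit.b, "c": wfit.c, "rmse": wfit.rmse}
        except (ValueError, FitError):
            pass
        summaries.append(CaseSummary(
            case_id=case_id,
            downselect=table,
            exposure_fraction_events=exposure_fraction(sub, threshold, "events"),
            exposure_fraction_peptides=exposure_fraction(sub, threshold, "peptides"),
            n_patterns=n_pat,
            entropy_bits=entropy,
            zip_wt=zw,
            zip_mut=zm,
            weibull=weibull,
        ))

    outdir = Path(outdir or r.get("outdir") or ".") if (outdir or r.get("outdir")) else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False, float_format="%.6g")
        pd.DataFrame([s.downselect.as_dict() for s in summaries]).to_csv(
            outdir / "downselect.tsv", sep="\t", index=False
        )
        payload = {
            "threshold": threshold,
            "dual_class_rule": r["dual_class_rule"],
            "seed": int(r["seed"]),
            "n_exclusions": len(exclusions),
            "exclusions": exclusions,
            "cases": [s.as_dict() for s in summaries],
        }
        (outdir / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return summaries, ann
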