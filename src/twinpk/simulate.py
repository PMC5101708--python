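"""Synthetic twin-cohort generator.

Builds cohorts with a known additive-genetic / dominance /
common-environment / unique-environment (A/D/C/E) decomposition of
log-clearance, Mendelian genotype sharing, covariates, and
one-compartment oral concentration–time profiles, so the downstream
non-compartmental analysis, twin variance-component modelling,
repeated-measures genetic component and association tests are all
testable without external data.

Component correlation structure within a pair: A correlates 1 in
monozygotic (MZ) and 0.5 in dizygotic (DZ) pairs, D correlates 1 (MZ)
and 0.25 (DZ), C correlates 1 in both, E is independent.  Components
act on the log scale, so clearances stay positive and the decomposition
stays additive.

A single seed drives every draw; per-table RNG streams are split from
one ``SeedSequence`` (phenotypes, genotypes, covariates, assay noise),
so e.g. adding a locus does not perturb the phenotype draws.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GenotypeLocus, SimulationConfig

__all__ = [
    "SimulatedCohort",
    "simulate_twin_phenotypes",
    "simulate_concentration_profiles",
    "simulate_genotypes_and_covariates",
    "simulate_cohort",
    "write_cohort",
]

DIET_ITEMS = (
    "meat",
    "sausage",
    "fish",
    "dairy_products",
    "eggs",
    "salad_raw_vegetable",
    "cooked_vegetable",
)


@dataclass
class SimulatedCohort:
    """Container for the three generated tables plus generating truth."""

    concentration_table: pd.DataFrame
    genotype_table: pd.DataFrame
    covariate_table: pd.DataFrame
    truth: dict


def _pair_frame(config: SimulationConfig) -> pd.DataFrame:
    """Subject/pair/zygosity skeleton: two subjects per pair."""
    rows = []
    pair = 0
    for zyg, n in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n):
            pair += 1
            for sib in (1, 2):
                rows.append(
                    {
                        "subject_id": f"S{pair:04d}{sib}",
                        "pair_id": f"P{pair:04d}",
                        "zygosity": zyg,
                        "sibling": sib,
                    }
                )
    return pd.DataFrame(rows)


def simulate_twin_phenotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-subject and per-occasion log-clearance with twin structure.

    Returns ``(subjects, occasions)``.  ``subjects`` carries the latent
    components (A, D, C, E) and the subject-level log-clearance
    ``log_cl`` (before genotype/covariate shifts); ``occasions`` adds
    log-normal occasion noise with natural-scale coefficient of
    variation ``within_subject_cv`` around the subject mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    subjects = _pair_frame(config)
    n_pairs = len(subjects) // 2
    sigma = config.log_cl_sd
    mz = (subjects["zygosity"] == "MZ").to_numpy()[::2]  # per pair

    def shared_component(prop: float, rho_dz: float) -> np.ndarray:
        """Per-subject draws with within-pair correlation 1 (MZ) / rho_dz (DZ)."""
        sd = sigma * np.sqrt(prop)
        common = rng.normal(0.0, 1.0, n_pairs)
        own = rng.normal(0.0, 1.0, (n_pairs, 2))
        rho = np.where(mz, 1.0, rho_dz)[:, None]
        vals = np.sqrt(rho) * common[:, None] + np.sqrt(1.0 - rho) * own
        return sd * vals.ravel()

    a = shared_component(config.a2, 0.5)
    d = shared_component(config.d2, 0.25)
    c = shared_component(config.c2, 1.0)
    e = sigma * np.sqrt(config.e2) * rng.normal(0.0, 1.0, 2 * n_pairs)

    # centre the natural-scale mean at mean_cl_l_per_min
    mu = np.log(config.mean_cl_l_per_min) - 0.5 * sigma**2
    subjects = subjects.assign(A=a, D=d, C=c, E=e, log_cl=mu + a + d + c + e)

    cv = config.within_subject_cv
    s2w = np.log1p(cv**2)
    noise = rng.normal(-0.5 * s2w, np.sqrt(s2w), (2 * n_pairs, config.n_occasions))
    occ = subjects.loc[subjects.index.repeat(config.n_occasions)].reset_index(drop=True)
    occ["occasion"] = np.tile(np.arange(1, config.n_occasions + 1), 2 * n_pairs)
    occ["log_cl_occasion"] = occ["log_cl"].to_numpy() + noise.ravel()
    occ = occ[["subject_id", "pair_id", "zygosity", "occasion", "log_cl_occasion"]]
    return subjects, occ


def one_compartment_concentration(
    t: np.ndarray, dose_mg: float, cl_l_per_min: float, vz_l: float, ka_per_h: float
) -> np.ndarray:
    """Noise-free one-compartment oral model, concentration in µg/l.

    C(t) = Dose·ka / (Vz·(ka − ke)) · (e^{−ke t} − e^{−ka t}),
    ke = 60·CL/Vz (1/h for CL in l/min).
    """
    ke = 60.0 * cl_l_per_min / vz_l
    ka = ka_per_h
    if abs(ka - ke) < 1e-12:  # flip-flop degeneracy; perturb
        ke *= 1.0 + 1e-9
    t = np.asarray(t, dtype=float)
    conc_mg_l = dose_mg * ka / (vz_l * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return 1000.0 * conc_mg_l


def simulate_concentration_profiles(
    occasions: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-simulate the concentration table from per-occasion clearance.

    ``occasions`` must carry ``log_cl_occasion`` (natural log of l/min).
    Multiplicative log-normal assay noise of CV ``assay_cv`` is applied;
    values below the lower limit of quantification are reported as
    missing with ``blq=True``.  The pre-dose (t=0) sample is zero and
    therefore always BLQ.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sampling_times_h)
    n = len(occasions)
    cl = np.exp(occasions["log_cl_occasion"].to_numpy())
    conc = np.empty((n, len(times)))
    for i, cli in enumerate(cl):
        conc[i] = one_compartment_concentration(
            times, config.dose_mg, cli, config.vz_l, config.ka_per_h
        )
    if config.assay_cv > 0:
        s2 = np.log1p(config.assay_cv**2)
        conc *= np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), conc.shape))
    conc[:, times == 0.0] = 0.0

    out = occasions.loc[occasions.index.repeat(len(times))].reset_index(drop=True)
    out["time_h"] = np.tile(times, n)
    flat = conc.ravel()
    blq = flat < config.lloq
    out["conc"] = np.where(blq, np.nan, flat)
    out["blq"] = blq
    out["dose_mg"] = config.dose_mg
    return out[
        ["subject_id", "pair_id", "zygosity", "occasion", "time_h", "conc", "blq", "dose_mg"]
    ]


# ---------------------------------------------------------------------------
# genotypes and covariates


def _haplotype_block(
    loci: list[GenotypeLocus], n: int, d_prime: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` haplotypes over the block's loci with pairwise-adjacent
    linkage disequilibrium D' (Lewontin's normalised D).

    Alleles are drawn as a Markov chain along the block: locus l given
    locus l-1 from the two-locus haplotype table with
    D = D'·min(p_{l-1}(1-p_l), (1-p_{l-1})p_l).
    """
    h = np.empty((n, len(loci)), dtype=np.int8)
    h[:, 0] = rng.random(n) < loci[0].frequency
    for j in range(1, len(loci)):
        p1, p2 = loci[j - 1].frequency, loci[j].frequency
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
        d = d_prime * dmax
        # conditional P(allele_j = 1 | allele_{j-1})
        p_given_1 = (p1 * p2 + d) / p1
        p_given_0 = ((1 - p1) * p2 - d) / (1 - p1)
        prev = h[:, j - 1] == 1
        pcond = np.where(prev, p_given_1, p_given_0)
        h[:, j] = rng.random(n) < pcond
    return h


def simulate_genotypes_and_covariates(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    geno_rng: np.random.Generator,
    covar_rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Generate the genotype and covariate tables plus the per-subject
    additive shift they contribute to log-clearance.

    MZ siblings receive identical genotypes; DZ siblings each inherit
    one haplotype from each of two simulated parents per block, so
    Mendelian sharing is exact.  The 23 zygosity loci are appended as
    independent biallelic markers.  Covariates: sex and age shared
    within pair, BMI = shared + unique normal components, seven diet
    questionnaire items as integer scores 1–6.
    """
    names = [l.name for l in config.genotype_loci]
    if len(set(names)) != len(names):
        raise ValueError("duplicated locus names")

    pairs = subjects.drop_duplicates("pair_id")
    n_pairs = len(pairs)
    mz = (pairs["zygosity"] == "MZ").to_numpy()

    zyg_freqs = 0.2 + 0.6 * (np.arange(config.n_zygosity_loci) % 5) / 4.0
    zyg_loci = [
        GenotypeLocus(f"ZYG{i+1:02d}", float(f)) for i, f in enumerate(zyg_freqs)
    ]

    blocks: list[list[GenotypeLocus]] = []
    seen: dict[int, list[GenotypeLocus]] = {}
    for locus in config.genotype_loci:
        if locus.block is None:
            blocks.append([locus])
        elif locus.block in seen:
            seen[locus.block].append(locus)
        else:
            seen[locus.block] = [locus]
            blocks.append(seen[locus.block])
    blocks.extend([l] for l in zyg_loci)

    all_names = [l.name for b in blocks for l in b]
    n_loci = len(all_names)
    geno = np.empty((2 * n_pairs, n_loci), dtype=np.int8)
    col = 0
    for block in blocks:
        w = len(block)
        # 4 parental haplotypes per pair
        hap = _haplotype_block(block, 4 * n_pairs, config.d_prime, geno_rng).reshape(
            n_pairs, 4, w
        )
        # sibling 1 inherits haplotype (0 or 1) from parent 1 and (2 or 3) from parent 2
        pick = geno_rng.integers(0, 2, size=(n_pairs, 2, 2))  # (pair, sib, parent)
        for sib in range(2):
            m = hap[np.arange(n_pairs), pick[:, sib, 0], :]
            p = hap[np.arange(n_pairs), 2 + pick[:, sib, 1], :]
            geno[sib::2, col : col + w] = m + p
        # MZ: sibling 2 is a genetic copy of sibling 1
        geno[1::2, col : col + w][mz] = geno[0::2, col : col + w][mz]
        col += w

    long = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects["subject_id"].to_numpy(), n_loci),
            "locus": np.tile(all_names, 2 * n_pairs),
            "allele_count": geno.ravel(),
        }
    )

    # covariates -----------------------------------------------------------
    sex_pair = (covar_rng.random(n_pairs) < 0.5).astype(int)  # same-sex pairs, 0=F 1=M
    age_pair = covar_rng.integers(18, 46, n_pairs)
    bmi_shared = covar_rng.normal(24.0, 2.0, n_pairs)
    bmi = np.clip(
        np.repeat(bmi_shared, 2) + covar_rng.normal(0.0, 1.5, 2 * n_pairs), 17, 35
    )
    diet_shared = covar_rng.normal(0.0, 0.6, (n_pairs, len(DIET_ITEMS)))
    diet = np.clip(
        np.rint(
            3.5
            + np.repeat(diet_shared, 2, axis=0)
            + covar_rng.normal(0.0, 1.0, (2 * n_pairs, len(DIET_ITEMS)))
        ),
        1,
        6,
    ).astype(int)

    covar = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "sex": np.repeat(sex_pair, 2),
            "age": np.repeat(age_pair, 2),
            "bmi": np.round(bmi, 1),
        }
    )
    for j, item in enumerate(DIET_ITEMS):
        covar[item] = diet[:, j]

    # additive log-clearance shift, centred so the cohort mean is unchanged
    protein = covar[["meat", "sausage", "fish", "dairy_products", "eggs"]].mean(axis=1)
    vegetable = covar[["salad_raw_vegetable", "cooked_vegetable"]].mean(axis=1)
    derived = {
        "sex": covar["sex"] - 0.5,
        "age": covar["age"] - 32.0,
        "bmi": covar["bmi"] - 24.0,
        "protein_score": protein - 3.5,
        "vegetable_score": vegetable - 3.5,
    }
    shift = np.zeros(2 * n_pairs)
    for name, eff in config.covariate_effects.items():
        if name not in derived:
            raise ValueError(f"unknown covariate effect {name!r}")
        shift += eff * derived[name].to_numpy()
    counts = pd.pivot_table(
        long, index="subject_id", columns="locus", values="allele_count", sort=False
    ).loc[subjects["subject_id"]]
    for locus in config.genotype_loci:
        if locus.effect:
            shift += locus.effect * (
                counts[locus.name].to_numpy() - 2.0 * locus.frequency
            )
    return long, covar, shift


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full generator: phenotypes + genotypes/covariates + concentrations."""
    ss = np.random.SeedSequence(config.seed)
    pheno_rng, geno_rng, covar_rng, assay_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    subjects, _ = simulate_twin_phenotypes(config, pheno_rng)
    geno, covar, shift = simulate_genotypes_and_covariates(
        config, subjects, geno_rng, covar_rng
    )
    subjects = subjects.assign(log_cl=subjects["log_cl"] + shift)

    # re-derive occasions around the shifted subject values
    cv = config.within_subject_cv
    s2w = np.log1p(cv**2)
    n_occ = config.n_occasions
    noise = pheno_rng.normal(-0.5 * s2w, np.sqrt(s2w), (len(subjects), n_occ))
    occ = subjects.loc[subjects.index.repeat(n_occ)].reset_index(drop=True)
    occ["occasion"] = np.tile(np.arange(1, n_occ + 1), len(subjects))
    occ["log_cl_occasion"] = occ["log_cl"].to_numpy() + noise.ravel()

    conc = simulate_concentration_profiles(occ, config, assay_rng)
    truth = {
        "config": config.to_dict(),
        "subjects": subjects[
            ["subject_id", "pair_id", "zygosity", "A", "D", "C", "E", "log_cl"]
        ].to_dict(orient="list"),
        "occasion_log_cl": occ[["subject_id", "occasion", "log_cl_occasion"]].to_dict(
            orient="list"
        ),
    }
    return SimulatedCohort(conc, geno, covar, truth)


def write_cohort(cohort: SimulatedCohort, out_dir: str) -> dict[str, str]:
    """Write concentrations.csv, genotypes.csv, covariates.csv, truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "concentrations": os.path.join(out_dir, "concentrations.csv"),
        "genotypes": os.path.join(out_dir, "genotypes.csv"),
        "covariates": os.path.join(out_dir, "covariates.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    cohort.concentration_table.to_csv(paths["concentrations"], index=False)
    cohort.genotype_table.to_csv(paths["genotypes"], index=False)
    cohort.covariate_table.to_csv(paths["covariates"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh)
    return paths
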