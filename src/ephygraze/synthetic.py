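"""Forward simulators for every pipeline stage.

These generators produce inputs with the statistical structure the
analysis assumes, so estimators can be exercised and parameter-recovery
experiments run without any field data:

* bottle counts from the exponential growth/grazing model, with Poisson
  counting error on the cells actually enumerated in a finite counted
  subvolume (Utermöhl-chamber counting statistics);
* OTU read counts from a Dirichlet-multinomial: group-level composition
  profiles, a concentration parameter controlling replicate tightness,
  multinomial sampling at fixed sequencing depth;
* assay signals (scintillation DPM, AMC fluorescence) generated by
  inverting the assay conversion chains from known true rates, with
  Poisson/Gaussian noise.

Every generator is a deterministic function of (truth, seed), and
noise-free generation composed with the corresponding estimator is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assays import (DPM_PER_CI, FluorescenceAssay, LeucineAssay,
                     heterotrophic_carbon_production)
from .core_io import (CountMatrix, MicrocosmDesign, OtuTable, SampleMeta,
                      load_table1_taxa, logger)

# Near-total-depletion grazing coefficient used when a target ingestion
# rate exceeds what zero prey growth allows (prey must be replenished).
_DEPLETION_G = 5.0


@dataclass
class SimulationTruth:
    """Ground truth for the microcosm forward model.

    ``count_subvolume`` is the volume (L) actually enumerated under the
    microscope and sets the Poisson counting noise; ``None`` disables
    counting noise entirely.
    """

    taxon_ids: list[str]
    c0_true: np.ndarray           # cells L⁻¹
    k_true: np.ndarray            # d⁻¹
    g_true: np.ndarray            # d⁻¹
    design: MicrocosmDesign = field(default_factory=MicrocosmDesign)
    count_subvolume: float | None = 0.5   # L settled and counted
    # community simulation
    otu_group_profiles: dict[str, np.ndarray] | None = None  # RA %, sum 100
    dirichlet_concentration: float = 200.0
    sequencing_depth: int = 20000
    # assay simulation
    hcp_true: float = 0.23              # μg C L⁻¹ h⁻¹
    amp_rate_true: float = 39.01        # nM h⁻¹ (ambient seawater)
    ephyra_amp_rate_true: float = 1083.47  # nM h⁻¹ ind⁻¹
    noise_sd_fluorescence: float = 0.5  # FU
    calib_slope: float = 2.0            # FU per nM
    calib_intercept: float = 50.0       # FU
    killed_dpm: float = 50.0
    blank_drift: float = 3.0            # FU over the incubation
    seed: int = 0


def _ingestion_from_rates(c0: float, k: float, g: float,
                          design: MicrocosmDesign) -> float:
    t = design.duration
    r = k - g
    cbar = c0 if abs(r) < 1e-12 else c0 * (np.exp(r * t) - 1.0) / (r * t)
    return g * design.volume / design.n_predators * cbar


def table1_like_truth(design: MicrocosmDesign | None = None,
                      count_subvolume: float | None = 0.5,
                      seed: int = 0) -> SimulationTruth:
    """Truth preset encoding the bundled 28-taxon reference table.

    Initial concentrations are the printed T0 abundances.  Controls are
    held constant (k = 0) and g is solved so the noise-free ingestion
    rate equals the printed per-ephyra rate; for the few taxa whose
    printed rate exceeds the zero-growth ceiling (V/n)·C0/t, grazing is
    set to near-total depletion and k is solved instead (the prey must
    have been replenished by growth).
    """
    design = design or MicrocosmDesign()
    df = load_table1_taxa()
    c0 = df["abundance_t0"].to_numpy(dtype=float)
    target = df["ingestion_cells"].to_numpy(dtype=float)
    k = np.zeros(len(df))
    g = np.zeros(len(df))
    for i, (c, i_target) in enumerate(zip(c0, target)):
        if i_target <= 0:
            continue
        ceiling = design.volume / design.n_predators * c / design.duration
        if i_target < 0.98 * ceiling:
            g[i] = brentq(lambda gg: _ingestion_from_rates(c, 0.0, gg, design) - i_target,
                          1e-9, 50.0)
        else:
            g[i] = _DEPLETION_G
            k[i] = brentq(lambda kk: _ingestion_from_rates(c, kk, g[i], design) - i_target,
                          0.0, g[i] - 1e-6)
    return SimulationTruth(list(df.index), c0, k, g, design,
                           count_subvolume=count_subvolume, seed=seed)


def null_grazing_truth(seed: int = 0,
                       count_subvolume: float | None = 0.5) -> SimulationTruth:
    """Same taxa and abundances as the reference preset but zero grazing
    everywhere (filter-specificity experiments)."""
    truth = table1_like_truth(count_subvolume=count_subvolume, seed=seed)
    truth.g_true = np.zeros_like(truth.g_true)
    truth.k_true = np.zeros_like(truth.k_true)
    return truth


def default_otu_profiles(n_otus: int = 60, shift: float = 1.0,
                         seed: int = 0) -> dict[str, np.ndarray]:
    """Group-level RA profiles (%) for a three-group design: T0 and the
    T24 controls share a composition, the T24 treatments are tilted by a
    lognormal factor of scale ``shift`` (0 → identical profiles)."""
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_otus, 0.5)) * 100.0
    tilt = np.exp(rng.normal(0.0, shift, size=n_otus))
    treated = base * tilt
    treated *= 100.0 / treated.sum()
    return {"T0": base, "T24C": base.copy(), "T24E": treated}


def _grazing_samples(design: MicrocosmDesign) -> list[SampleMeta]:
    samples = [SampleMeta(f"T0_{r}", "T0", "control", r)
               for r in range(1, design.n_control_reps + 1)]
    samples += [SampleMeta(f"T24_C{r}", "T24", "control", r)
                for r in range(1, design.n_control_reps + 1)]
    samples += [SampleMeta(f"T24_E{r}", "T24", "treatment", r)
                for r in range(1, design.n_treatment_reps + 1)]
    return samples


def simulate_grazing_experiment(truth: SimulationTruth,
                                seed: int | None = None) -> CountMatrix:
    """Bottle counts (cells L⁻¹) for T0 / T24-control / T24-treatment.

    Expectations follow the exponential model; observed concentrations
    are Poisson(expectation × subvolume)/subvolume, or the expectations
    exactly when ``count_subvolume`` is None.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    design = truth.design
    t = design.duration
    samples = _grazing_samples(design)
    c0 = np.asarray(truth.c0_true, dtype=float)
    exp_ctrl = c0 * np.exp(truth.k_true * t)
    exp_treat = c0 * np.exp((truth.k_true - truth.g_true) * t)

    def observe(expect: np.ndarray) -> np.ndarray:
        if truth.count_subvolume is None:
            return expect.copy()
        v = truth.count_subvolume
        return rng.poisson(expect * v) / v

    data = {}
    for s in samples:
        expect = c0 if s.timepoint == "T0" else (
            exp_ctrl if s.condition == "control" else exp_treat)
        data[s.sample_id] = observe(expect)
    df = pd.DataFrame(data, index=truth.taxon_ids)
    logger.info("simulate_grazing_experiment: %d taxa, subvolume=%s L",
                len(truth.taxon_ids), truth.count_subvolume)
    return CountMatrix(df, samples)


def simulate_otu_table(truth: SimulationTruth, groups: list[str],
                       reps_per_group: int = 3,
                       seed: int | None = None,
                       lineages: pd.Series | None = None) -> OtuTable:
    """Dirichlet-multinomial OTU counts: per sample the composition is
    Dirichlet(concentration × group profile) and counts are
    Multinomial(depth, composition)."""
    if truth.otu_group_profiles is None:
        raise ValueError("truth.otu_group_profiles is not set")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    profiles = truth.otu_group_profiles
    n_otus = len(next(iter(profiles.values())))
    otu_ids = [f"otu_{i:04d}" for i in range(n_otus)]
    if lineages is None:
        lineages = pd.Series(
            [f"Eukaryota;Phylum_{i % 5};Class_{i % 9};Order_{i % 13};Family_{i}"
             for i in range(n_otus)], index=otu_ids)
    counts = {}
    samples = []
    group_of_sample = {}
    rep_counter: dict[tuple[str, str], int] = {}
    for group in groups:
        profile = np.asarray(profiles[group], dtype=float)
        alpha = truth.dirichlet_concentration * profile / profile.sum()
        alpha = np.clip(alpha, 1e-9, None)
        timepoint = "T0" if group.upper().startswith("T0") else "T24"
        condition = "treatment" if group.upper().endswith("E") else "control"
        for rep in range(1, reps_per_group + 1):
            sid = f"{group}_{rep}"
            comp = rng.dirichlet(alpha)
            counts[sid] = rng.multinomial(truth.sequencing_depth, comp)
            # replicate numbering must be unique per design cell even when
            # several groups map onto the same (timepoint, condition)
            key = (timepoint, condition)
            rep_counter[key] = rep_counter.get(key, 0) + 1
            samples.append(SampleMeta(sid, timepoint, condition, rep_counter[key]))
            group_of_sample[sid] = group
    table = OtuTable(pd.DataFrame(counts, index=otu_ids), lineages, samples)
    table.counts.attrs["groups"] = group_of_sample
    return table


def simulate_assays(truth: SimulationTruth, noise: bool = True,
                    seed: int | None = None,
                    n_replicates: int = 2,
                    sample_volume_ml: float = 1.7,
                    incubation_h: float = 1.0):
    """Generate one leucine assay, one bulk fluorescence assay, one
    diluted predator-vial fluorescence assay, and AMC standards, all by
    inverting the assay conversion chains from the true rates.

    Returns ``(leucine, fluor_bulk, fluor_vial, standards)`` where
    ``standards`` is a list of (concentration nM, fluorescence FU).
    With ``noise=False`` the estimators recover the truth exactly.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    # --- leucine incorporation from hcp_true ---
    leu_rate = truth.hcp_true / heterotrophic_carbon_production(1.0)  # nmol L⁻¹ h⁻¹
    nmol = leu_rate * (sample_volume_ml / 1000.0) * incubation_h
    signal_dpm = nmol * 1e-6 * 52.9 * DPM_PER_CI  # nmol → mmol → Ci → DPM
    expected = signal_dpm + truth.killed_dpm
    if noise:
        dpm = tuple(float(rng.poisson(expected)) for _ in range(n_replicates))
        killed = float(rng.poisson(truth.killed_dpm))
    else:
        dpm = (expected,) * n_replicates
        killed = truth.killed_dpm
    leucine = LeucineAssay(dpm, killed, sample_volume_ml, incubation_h, 52.9)

    # --- fluorescence from amp_rate_true via the known calibration line ---
    def fluor(rate_nm_h: float, dilution: float) -> FluorescenceAssay:
        f0 = truth.calib_intercept + 10.0   # arbitrary positive baseline
        dF = truth.calib_slope * rate_nm_h * incubation_h + truth.blank_drift
        b0 = truth.calib_intercept
        b1 = b0 + truth.blank_drift
        vals = np.array([f0, f0 + dF, b0, b1])
        if noise:
            vals = vals + rng.normal(0.0, truth.noise_sd_fluorescence, size=4)
        return FluorescenceAssay(vals[0], vals[1], vals[2], vals[3],
                                 incubation_h, dilution)

    fluor_bulk = fluor(truth.amp_rate_true, 1.0)
    # vial holds 1/D ambient seawater plus one predator's consortium, diluted D-fold
    dilution = 10.0
    vial_rate = (truth.amp_rate_true + truth.ephyra_amp_rate_true) / dilution
    fluor_vial = fluor(vial_rate, dilution)

    concs = [0.0, 100.0, 200.0, 400.0]
    standards = []
    for c in concs:
        for _ in range(3):
            f = truth.calib_intercept + truth.calib_slope * c
            if noise:
                f += rng.normal(0.0, truth.noise_sd_fluorescence)
            standards.append((c, float(f)))
    return leucine, fluor_bulk, fluor_vial, standards
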