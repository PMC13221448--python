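"""Synthetic single-slide FFPE DIA cohort generator.

The generator emulates the statistical structure of gene-centric DIA
proteomics from minute FFPE inputs, not its spectral detail: a wide
(~5 decades) protein dynamic range, per-biopsy tissue-compartment
mixtures (AC tumor, SCC tumor, immune, normal epithelium), additive
blood and skin-keratin contamination whose signal load suppresses
identifications via a detection-threshold shift, abundance-dependent
(left-censored) missingness with a global-imputation twin, per-sample
total-MS1 signal that follows a saturating quadratic calibration curve
in log-log space, and instrument-specific depth/noise. Ground truth
(compartment fractions, extracted/injected peptide masses, marker
effects) is returned alongside the data for recovery tests.

Compartment profiles are normalized relative signal compositions, so a
compartment's mixture fraction equals the fraction of total MS signal
it contributes — which makes the contamination -> suppression coupling
exact and directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from .errors import ConfigurationError
from .io import packaged_signatures

COMPARTMENTS = (
    "tumor_AC",
    "tumor_SCC",
    "immune",
    "normal_epithelium",
    "blood",
    "keratin",
)

#: genes boosted heavily in the keratin-contaminant compartment (flakes)
_CORE_SKIN_KERATINS = ("KRT1", "KRT2", "KRT9", "KRT10")
_MINOR_SKIN_KERATINS = ("KRT5", "KRT6A", "KRT14", "KRT16", "KRT17")
_BLOOD_GENES = {"HBB": 3.0, "HBA1": 2.8, "ALB": 2.2, "HP": 1.5, "TF": 1.5}

#: biopsy-type Dirichlet weights over (tumor, immune, normal epithelium);
#: forceps biopsies carry more normal epithelium than core/cryo needles
_TISSUE_ALPHAS = {
    "core": (5.0, 2.0, 2.0),
    "forceps": (3.5, 2.0, 4.5),
    "cryo": (5.0, 2.0, 2.0),
}

#: biopsy length distributions, mm: (mean, sd, low, high)
_LENGTH_PARAMS = {
    "core": (10.0, 4.0, 2.0, 25.0),
    "forceps": (4.0, 1.5, 1.0, 10.0),
    "cryo": (15.0, 8.0, 3.0, 40.0),
}

_PEPTIDE_GEOM_P = 0.45
_MAX_PEPTIDES = 8
_DETECTION_STEEPNESS = 0.25  # decades
_NOISE_WEIGHT_SCALE = 2.5  # decades over which suppression noise decays
_YIELD_NG_PER_MM = 25.0
_YIELD_LOGNORM_SIGMA = 0.35


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a 68-sample single-slide cohort measured on an
    Orbitrap-Astral-class instrument with ~7000 expected identifications
    for a clean sample, 10% measurement CV, and a heavy-tailed
    log-normal keratin contamination load.
    """

    n_samples: int = 68
    n_proteins: int = 9000
    biopsy_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {"core": 0.5, "forceps": 0.35, "cryo": 0.15}
    )
    histology_probs: Mapping[str, float] = field(
        default_factory=lambda: {"AC": 0.6, "SCC": 0.4}
    )
    dynamic_range_log10: float = 5.0
    contamination_level: Mapping[str, float] = field(
        default_factory=lambda: {
            "keratin_median": 0.06,
            "keratin_sigma": 1.0,
            "blood_median": 0.02,
            "blood_sigma": 0.8,
        }
    )
    suppression_strength: float = 20.0
    noise_suppression: float = 30.0
    detection_capacity: float = 7000.0
    noise_cv: float = 0.10
    missing_rate_params: Mapping[str, float] = field(
        default_factory=lambda: {"steepness_decades": _DETECTION_STEEPNESS, "midpoint_shift": 0.0}
    )
    instrument_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "astral": {"depth_multiplier": 1.0, "noise_multiplier": 1.0},
            "timstof": {"depth_multiplier": 0.93, "noise_multiplier": 1.3},
        }
    )
    instrument: str = "astral"
    curve_truth: tuple[float, float, float] = (2.0, 0.9, -0.02)
    injection_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_samples < 2:
            raise ConfigurationError("n_samples: must be >= 2")
        if self.n_proteins < 10:
            raise ConfigurationError("n_proteins: must be >= 10")
        if not self.noise_cv > 0:
            raise ConfigurationError("noise_cv: must be > 0")
        for name, probs in (
            ("biopsy_type_probs", self.biopsy_type_probs),
            ("histology_probs", self.histology_probs),
        ):
            vals = np.asarray(list(probs.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: probabilities must be >= 0 and sum to 1")
        for key, val in self.contamination_level.items():
            if val < 0:
                raise ConfigurationError(f"contamination_level.{key}: must be >= 0")
        if self.instrument not in self.instrument_profiles:
            raise ConfigurationError(
                f"instrument: {self.instrument!r} not in instrument_profiles"
            )
        return self


@dataclass
class SimTruth:
    """Ground truth emitted with a simulated cohort."""

    samples: pd.DataFrame  # per-sample: lengths, masses, contaminant fraction
    fractions: pd.DataFrame  # samples x compartments, rows sum to 1
    profiles: pd.DataFrame  # proteins x compartments relative compositions
    compartments: tuple[str, ...]
    immune_genes: tuple[str, ...]
    immune_effect_log2: float
    curve_truth: tuple[float, float, float]


class CohortData(NamedTuple):
    """All artifacts of one simulated measurement of a cohort."""

    precursors: pd.DataFrame
    quant: pd.DataFrame  # non-imputed protein x sample matrix, linear scale
    quant_imputed: pd.DataFrame
    imputed_mask: pd.DataFrame
    tic: pd.DataFrame
    meta: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# gene universe and compartment profiles


def _gene_universe(n_proteins: int) -> list[str]:
    sigs = packaged_signatures()
    special: dict[str, None] = {}
    for sig in sigs.values():
        for g in sig.genes:
            special.setdefault(g, None)
    for g in _BLOOD_GENES:
        special.setdefault(g, None)
    names = list(special)[: max(0, n_proteins - 5)]
    fillers = (f"G{i:05d}" for i in range(1, n_proteins + 1))
    while len(names) < n_proteins:
        names.append(next(fillers))
    return names[:n_proteins]


def _immune_gene_set() -> tuple[str, ...]:
    sigs = packaged_signatures()
    pool: dict[str, None] = {}
    for name in (
        "TIS",
        "IMMUNE_CELL_MARKERS_SYNTHETIC",
        "IFNG_RESPONSE_SYNTHETIC",
        "INFLAMMATORY_RESPONSE_SYNTHETIC",
    ):
        for g in sigs[name].genes:
            pool.setdefault(g, None)
    return tuple(pool)


def _compartment_profiles(
    genes: Sequence[str], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Relative signal composition of each compartment (columns sum to 1)."""
    sigs = packaged_signatures()
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(0.0, config.dynamic_range_log10 / 4.0, size=n)
    # pin QC-relevant marker genes to mid/high abundance so they are
    # reliably detectable in clean samples
    for g in sigs["MCM_COMPLEX"].genes:
        if g in idx:
            base[idx[g]] = rng.normal(0.3, 0.1)
    for g in _immune_gene_set():
        if g in idx:
            base[idx[g]] = rng.normal(0.0, 0.4)
    for panel in ("AC_MARKERS", "SCC_MARKERS"):
        for g in sigs[panel].genes:
            if g in idx:
                base[idx[g]] = rng.normal(0.5, 0.3)

    delta = np.zeros((n, len(COMPARTMENTS)))
    cix = {c: j for j, c in enumerate(COMPARTMENTS)}
    # mild idiosyncratic tissue variation so profiles are not collinear
    delta[:, : cix["blood"]] += rng.normal(0.0, 0.15, size=(n, 4))

    def bump(gene: str, comp: str, amount: float) -> None:
        if gene in idx:
            delta[idx[gene], cix[comp]] += amount

    for g in _immune_gene_set():
        bump(g, "immune", 1.2)
    for g in sigs["AC_MARKERS"].genes:
        bump(g, "tumor_AC", 1.2)
        bump(g, "tumor_SCC", -0.5)
    for g in sigs["SCC_MARKERS"].genes:
        bump(g, "tumor_SCC", 1.2)
        bump(g, "tumor_AC", -0.5)
    # blood: plasma background plus strongly boosted blood proteins
    delta[:, cix["blood"]] -= 1.0
    for g, amt in _BLOOD_GENES.items():
        bump(g, "blood", amt + 1.0)
    # keratin contaminant: essentially only keratins carry signal
    delta[:, cix["keratin"]] -= 6.0
    for g in _CORE_SKIN_KERATINS:
        bump(g, "keratin", 6.0 + 3.5)
    for g in _MINOR_SKIN_KERATINS:
        bump(g, "keratin", 6.0 + 2.0)

    log_prof = base[:, None] + delta
    prof = np.power(10.0, log_prof - log_prof.max(axis=0, keepdims=True))
    prof /= prof.sum(axis=0, keepdims=True)
    return pd.DataFrame(prof, index=list(genes), columns=list(COMPARTMENTS))


# ---------------------------------------------------------------------------
# per-sample truth


def _make_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    n = config.n_samples
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    genes = _gene_universe(config.n_proteins)
    profiles = _compartment_profiles(genes, config, rng)

    btypes = rng.choice(
        list(config.biopsy_type_probs), p=list(config.biopsy_type_probs.values()), size=n
    )
    histo = rng.choice(
        list(config.histology_probs), p=list(config.histology_probs.values()), size=n
    )

    cl = config.contamination_level
    ker = np.exp(rng.normal(np.log(max(cl["keratin_median"], 1e-12)), cl["keratin_sigma"], n))
    blood = np.exp(rng.normal(np.log(max(cl["blood_median"], 1e-12)), cl["blood_sigma"], n))
    if cl["keratin_median"] == 0:
        ker = np.zeros(n)
    if cl["blood_median"] == 0:
        blood = np.zeros(n)
    contam = ker + blood
    over = contam > 0.8
    scale = np.where(over, 0.8 / np.maximum(contam, 1e-12), 1.0)
    ker, blood = ker * scale, blood * scale

    fractions = np.zeros((n, len(COMPARTMENTS)))
    lengths = np.zeros(n)
    for i in range(n):
        a = _TISSUE_ALPHAS[btypes[i]]
        tumor, immune, normal = rng.dirichlet(a)
        tissue_total = 1.0 - ker[i] - blood[i]
        row = {
            "tumor_AC": tumor * tissue_total if histo[i] == "AC" else 0.0,
            "tumor_SCC": tumor * tissue_total if histo[i] == "SCC" else 0.0,
            "immune": immune * tissue_total,
            "normal_epithelium": normal * tissue_total,
            "blood": blood[i],
            "keratin": ker[i],
        }
        fractions[i] = [row[c] for c in COMPARTMENTS]
        mu, sd, lo, hi = _LENGTH_PARAMS[btypes[i]]
        lengths[i] = float(np.clip(rng.normal(mu, sd), lo, hi))

    extracted = (
        _YIELD_NG_PER_MM * lengths * np.exp(rng.normal(0.0, _YIELD_LOGNORM_SIGMA, n))
    )
    injected = config.injection_fraction * extracted

    frac_df = pd.DataFrame(fractions, index=sample_ids, columns=list(COMPARTMENTS))
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "biopsy_type": btypes,
            "histology": histo,
            "biopsy_length_mm": np.round(lengths, 2),
            "true_extracted_peptide_ng": extracted,
            "true_injected_ng": injected,
            "contaminant_signal_fraction": frac_df["blood"] + frac_df["keratin"],
            "immune_fraction": frac_df["immune"].to_numpy(),
        },
        index=sample_ids,
    )
    return SimTruth(
        samples=samples,
        fractions=frac_df,
        profiles=profiles,
        compartments=COMPARTMENTS,
        immune_genes=_immune_gene_set(),
        immune_effect_log2=1.2 * np.log2(10.0),
        curve_truth=tuple(config.curve_truth),
    )


# ---------------------------------------------------------------------------
# measurement model


def _solve_detection_midpoint(
    log_ref: np.ndarray, capacity: float, steepness: float
) -> float:
    """Midpoint such that expected detections on a clean reference mixture
    equal ``capacity``."""
    capacity = min(capacity, 0.95 * log_ref.size)

    def gap(m: float) -> float:
        return float(expit((log_ref - m) / steepness).sum() - capacity)

    lo, hi = log_ref.min() - 5.0, log_ref.max() + 5.0
    return float(brentq(gap, lo, hi, xtol=1e-9))


def _curve_signal(coeffs: Sequence[float], amount_ng: np.ndarray) -> np.ndarray:
    c0, c1, c2 = coeffs
    x = np.log10(np.asarray(amount_ng, dtype=float))
    return np.power(10.0, c0 + c1 * x + c2 * x**2)


def _measure(truth: SimTruth, config: SimConfig, instrument: str, rng: np.random.Generator) -> CohortData:
    prof = truth.profiles.to_numpy()
    genes = list(truth.profiles.index)
    sample_ids = list(truth.samples.index)
    n_prot, n_samp = len(genes), len(sample_ids)
    iprof = config.instrument_profiles[instrument]
    steep = config.missing_rate_params.get("steepness_decades", _DETECTION_STEEPNESS)
    mshift = config.missing_rate_params.get("midpoint_shift", 0.0)

    fr = truth.fractions.to_numpy()  # samples x compartments
    mix = prof @ fr.T  # proteins x samples, columns sum to 1
    logmix = np.log10(np.maximum(mix, 1e-300))
    contam = truth.samples["contaminant_signal_fraction"].to_numpy()

    # detection: logistic in log10 relative abundance, midpoint shifted by
    # the contaminant signal load (ion-suppression emulation)
    tissue = fr[:, :4].mean(axis=0)
    tissue = tissue / tissue.sum()
    ref = prof[:, :4] @ tissue
    logref = np.log10(np.maximum(ref, 1e-300))
    m0 = _solve_detection_midpoint(
        logref, config.detection_capacity * iprof["depth_multiplier"], steep
    )
    midpoints = m0 + mshift + np.log10(1.0 + config.suppression_strength * contam)
    p_det = expit((logmix - midpoints[None, :]) / steep)
    detected = rng.random((n_prot, n_samp)) < p_det

    # measurement noise: base CV inflated near the detection limit in
    # contaminated samples (suppression degrades low-signal quantification)
    wlow = expit(-(logmix - midpoints[None, :]) / _NOISE_WEIGHT_SCALE)
    sigma = (
        config.noise_cv
        * iprof["noise_multiplier"]
        * (1.0 + config.noise_suppression * contam[None, :] * wlow)
    )
    noise = np.exp(rng.normal(0.0, 1.0, size=(n_prot, n_samp)) * sigma)

    ms2_scale = 1e9 * np.exp(rng.normal(0.0, 0.2, n_samp))
    quant_full = mix * noise * ms2_scale[None, :]
    quant = pd.DataFrame(
        np.where(detected, quant_full, np.nan), index=genes, columns=sample_ids
    )

    # global-imputation twin: left-shifted draws below each sample's
    # observed log2 distribution (downshift 1.8 SD, spread 0.3 SD)
    logq = np.log2(quant.to_numpy())
    mu = np.nanmean(logq, axis=0)
    sd = np.nanstd(logq, axis=0, ddof=1)
    fill = np.power(
        2.0,
        rng.normal(
            (mu - 1.8 * sd)[None, :].repeat(n_prot, 0),
            (0.3 * sd)[None, :].repeat(n_prot, 0),
        ),
    )
    quant_imputed = pd.DataFrame(
        np.where(detected, quant_full, fill), index=genes, columns=sample_ids
    )
    imputed_mask = pd.DataFrame(~detected, index=genes, columns=sample_ids)

    # total MS1 follows the saturating calibration curve in the injected
    # amount; per-protein MS1 splits the total by detected relative signal
    injected = truth.samples["true_injected_ng"].to_numpy()
    total_ms1 = _curve_signal(truth.curve_truth, injected) * np.exp(
        rng.normal(0.0, config.noise_cv, n_samp)
    )
    det_sig = np.where(detected, mix, 0.0)
    det_sig = det_sig / det_sig.sum(axis=0, keepdims=True)
    prot_ms1 = det_sig * total_ms1[None, :]

    precursors = _build_precursors(genes, sample_ids, detected, prot_ms1, rng)
    tic = _build_tic(sample_ids, total_ms1, rng)
    meta = _build_meta(truth, instrument, rng)
    return CohortData(precursors, quant, quant_imputed, imputed_mask, tic, meta, truth)


def _build_precursors(
    genes: Sequence[str],
    sample_ids: Sequence[str],
    detected: np.ndarray,
    prot_ms1: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_prot = len(genes)
    n_pep = 1 + np.minimum(rng.geometric(_PEPTIDE_GEOM_P, n_prot) - 1, _MAX_PEPTIDES - 1)
    offsets = np.concatenate([[0], np.cumsum(n_pep)])
    shares = np.concatenate(
        [rng.dirichlet(np.ones(k)) for k in n_pep]
    )
    pep_names = np.array(
        [f"{genes[p]}.p{j + 1}" for p in range(n_prot) for j in range(n_pep[p])],
        dtype=object,
    )

    pidx, sidx = np.nonzero(detected)
    counts = n_pep[pidx]
    total = int(counts.sum())
    row_p = np.repeat(pidx, counts)
    row_s = np.repeat(sidx, counts)
    starts = np.cumsum(counts) - counts
    within = np.arange(total) - np.repeat(starts, counts)
    flat = offsets[row_p] + within

    ms1 = (
        prot_ms1[row_p, row_s]
        * shares[flat]
        * np.exp(rng.normal(0.0, 0.05, total))
    )
    gene_arr = np.asarray(genes, dtype=object)
    samp_arr = np.asarray(sample_ids, dtype=object)
    return pd.DataFrame(
        {
            "sample_id": samp_arr[row_s],
            "protein": gene_arr[row_p],
            "peptide_id": pep_names[flat],
            "ms1_area": ms1,
            "detected": True,
        }
    )


def _build_tic(
    sample_ids: Sequence[str], total_ms1: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    t = np.linspace(0.0, 44.0, 89)
    bump = gamma_dist.pdf(t, a=4.0, scale=5.0) + 1e-3
    base_auc = np.trapezoid(bump, t)
    frames = []
    for i, sid in enumerate(sample_ids):
        target = total_ms1[i] * np.exp(rng.normal(0.0, 0.05))
        frames.append(
            pd.DataFrame(
                {"sample_id": sid, "time_min": t, "intensity": bump * target / base_auc}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _build_meta(truth: SimTruth, instrument: str, rng: np.random.Generator) -> pd.DataFrame:
    s = truth.samples
    p_pos = expit(-0.5 + 4.0 * s["immune_fraction"].to_numpy())
    pdl1 = np.where(rng.random(len(s)) < p_pos, "positive", "negative")
    unknown = rng.random(len(s)) < 0.05
    pdl1 = np.where(unknown, "unknown", pdl1)
    meta = pd.DataFrame(
        {
            "sample_id": s["sample_id"],
            "cohort": "single_slide",
            "biopsy_type": s["biopsy_type"],
            "histology": s["histology"],
            "pdl1_status": pdl1,
            "biopsy_length_mm": s["biopsy_length_mm"],
            "instrument": instrument,
            "injected_ng": s["true_injected_ng"].round(4),
        },
        index=s.index,
    )
    return meta


# ---------------------------------------------------------------------------
# public API


def simulate_cohort(config: SimConfig | None = None) -> CohortData:
    """Simulate one cohort measured on ``config.instrument``.

    Deterministic given ``config.seed``; all five artifacts share the
    same sample identifiers and derive from a single ground truth.
    """
    config = (config or SimConfig()).validate()
    ss = np.random.SeedSequence(config.seed)
    truth_seed, *instr_seeds = ss.spawn(1 + len(config.instrument_profiles))
    truth = _make_truth(config, np.random.default_rng(truth_seed))
    order = list(config.instrument_profiles)
    rng = np.random.default_rng(instr_seeds[order.index(config.instrument)])
    return _measure(truth, config, config.instrument, rng)


def simulate_two_instruments(config: SimConfig | None = None) -> dict[str, CohortData]:
    """Measure the same ground-truth cohort on every configured instrument.

    The first instrument's output is identical to :func:`simulate_cohort`
    with the same seed; later instruments share the truth but have
    independent measurement noise, detection and depth.
    """
    config = (config or SimConfig()).validate()
    ss = np.random.SeedSequence(config.seed)
    truth_seed, *instr_seeds = ss.spawn(1 + len(config.instrument_profiles))
    truth = _make_truth(config, np.random.default_rng(truth_seed))
    out = {}
    for instr, seed in zip(config.instrument_profiles, instr_seeds):
        out[instr] = _measure(truth, config, instr, np.random.default_rng(seed))
    return out


def simulate_hela_series(
    amounts_ng: Sequence[float],
    curve_truth: Sequence[float] = (2.0, 0.9, -0.02),
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a HeLa dilution-series standards table.

    ``total_ms1 = 10^(c0 + c1*log10(a) + c2*log10(a)^2)`` times
    log-normal noise with coefficient of variation ``cv``.
    """
    amounts = np.asarray(amounts_ng, dtype=float)
    if (amounts <= 0).any():
        raise ConfigurationError("amounts_ng: all amounts must be positive")
    if cv < 0:
        raise ConfigurationError("cv: must be >= 0")
    c0, c1, c2 = curve_truth
    x = np.log10(amounts)
    slope = c1 + 2.0 * c2 * np.array([x.min(), x.max()])
    if (slope <= 0).any():
        raise ConfigurationError(
            "curve_truth: calibration truth not monotone increasing over the amount range"
        )
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, cv, amounts.size)) if cv > 0 else 1.0
    return pd.DataFrame(
        {"amount_ng": amounts, "total_ms1": _curve_signal(curve_truth, amounts) * noise}
    )
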