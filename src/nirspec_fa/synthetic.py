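"""Synthetic NIR spectra and reference chemistry with realistic structure.

The generator emulates the data regime of freeze-dried beef NIRS work:

* **Concentrations.**  Each sample has a latent "carcass fatness" factor.
  Per fatty acid, the phospholipid concentration is drawn lognormal with the
  (low) phospholipid-fraction CV and only weak dependence on the latent
  factor — membrane lipid is physiologically buffered — while the neutral
  (storage) part is drawn lognormal with strong latent-factor dependence and
  a dispersion chosen so the *total* (= phospholipid + neutral) matches the
  target total-fraction mean and CV.  Construction therefore guarantees
  phospholipid <= total per analyte and sample.  Group sums (SFA, MUFA,
  PUFA) are sums of their constituents; TotalFA additionally carries an
  unreported-remainder component, so SFA+MUFA+PUFA <= TotalFA always holds.
  Default means and CVs are the calibration-set statistics of the reference
  study (see :mod:`nirspec_fa.reference_data`).

* **Spectra.**  Beer-Lambert-style linear mixing: each fatty acid owns a
  small set of Gaussian absorption bands concentrated in the C-H first
  overtone (~1700-1770 nm) and C-H combination (2200-2500 nm, peaks near
  2310/2348 nm) regions, with band sharing across chemically similar acids
  to induce the collinearity that limits minor-analyte calibrations.  The
  baseline rises from ~0.4 at 1000 nm towards ~1.0 at 2500 nm and carries
  *no* water bands (1440-1470 / 1920-1960 nm stay quiet), emulating
  freeze-dried material.  Multiplicative scatter (random gain), additive
  offset, a random linear tilt and white noise complete the model:

      x(lam) = gain * [baseline(lam) + sum_j c_j k_j(lam)] + offset
               + tilt * lam_norm + noise(lam)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .reference_data import (
    DESCRIPTIVE,
    MUFA_MEMBERS,
    PUFA_MEMBERS,
    SFA_MEMBERS,
)
from .spectra_io import (
    DEFAULT_GRID,
    FATTY_ACIDS,
    Spectrum,
    WavelengthGrid,
    write_reference,
    write_spectra,
)

GROUP_MEMBERS = {"SFA": SFA_MEMBERS, "MUFA": MUFA_MEMBERS, "PUFA": PUFA_MEMBERS}


@dataclass(frozen=True)
class AnalytePrior:
    """Target marginal for one analyte in one fraction (mg/100 g meat)."""

    name: str
    fraction: str
    mean: float
    cv: float  # percent

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ConfigurationError(f"negative mean for {self.name}")
        if self.mean > 0 and self.cv <= 0:
            raise ConfigurationError(f"non-positive CV for {self.name}")

    @property
    def sd(self) -> float:
        return self.mean * self.cv / 100.0


def default_priors() -> dict[tuple[str, str], AnalytePrior]:
    """Priors for every (fraction, fatty acid) from the reference-study
    calibration statistics."""
    priors = {}
    for fraction, table in DESCRIPTIVE.items():
        for name in FATTY_ACIDS:
            mean, _, _, sd, cv = table[name]["calibration"]
            priors[(fraction, name)] = AnalytePrior(name, fraction, mean, cv)
    return priors


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults are the emulated study regime."""

    n_samples: int = 332
    seed: int = 0
    scatter_gain_sd: float = 0.1
    scatter_offset_sd: float = 0.02
    baseline_tilt_sd: float = 0.01
    noise_sd: float = 0.005
    #: Gaussian-copula correlation of neutral-lipid draws with the latent
    #: fatness factor (storage fat tracks carcass fatness closely).
    rho_neutral: float = 0.95
    #: ... and of phospholipid draws (membrane lipid is nearly constant).
    rho_phospholipid: float = 0.3

    def __post_init__(self) -> None:
        for f in ("scatter_gain_sd", "scatter_offset_sd", "baseline_tilt_sd",
                  "noise_sd"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if self.n_samples < 2:
            raise ConfigurationError("need at least 2 samples")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment inversion: (mu, sigma) of a lognormal with given mean and SD."""
    if mean <= 0:
        raise ConfigurationError("lognormal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _copula_lognormal(rng, z_latent, mean, sd, rho):
    """Lognormal draws with target moments, Gaussian-copula-linked to z_latent."""
    if mean == 0:
        return np.zeros_like(z_latent)
    mu, sigma = _lognormal_params(mean, sd)
    z = rho * z_latent + np.sqrt(1 - rho**2) * rng.standard_normal(z_latent.size)
    return np.exp(mu + sigma * z)


def simulate_concentrations(
    config: SimulationConfig,
    priors: dict[tuple[str, str], AnalytePrior] | None = None,
) -> pd.DataFrame:
    """Draw a long-format reference table of concentrations.

    Returns a DataFrame with columns ``sample_id, fraction, analyte,
    value_mg_per_100g`` covering the 20 fatty acids and the four group sums
    in both fractions.
    """
    priors = priors or default_priors()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    z_latent = rng.standard_normal(n)

    phospho: dict[str, np.ndarray] = {}
    total: dict[str, np.ndarray] = {}
    for name in FATTY_ACIDS:
        pp = priors[("phospholipid", name)]
        pt = priors[("total", name)]
        p_vals = _copula_lognormal(rng, z_latent, pp.mean, pp.sd,
                                   config.rho_phospholipid)
        neutral_mean = pt.mean - pp.mean
        if neutral_mean <= 1e-9 * max(pt.mean, 1.0):
            n_vals = np.zeros(n)
        else:
            # Neutral dispersion chosen so the total hits its target SD
            # (variances approximately add; the weak phospho-neutral coupling
            # through the latent factor is a second-order effect).
            neutral_sd = np.sqrt(max(pt.sd**2 - pp.sd**2, (0.1 * pt.sd) ** 2))
            n_vals = _copula_lognormal(rng, z_latent, neutral_mean, neutral_sd,
                                       config.rho_neutral)
        phospho[name] = p_vals
        total[name] = p_vals + n_vals

    # Group sums from constituents; TotalFA adds the unreported remainder so
    # that SFA + MUFA + PUFA <= TotalFA by construction.
    for frac_vals, frac_name in ((phospho, "phospholipid"), (total, "total")):
        for group, members in GROUP_MEMBERS.items():
            frac_vals[group] = np.sum([frac_vals[m] for m in members], axis=0)
        group_sum = frac_vals["SFA"] + frac_vals["MUFA"] + frac_vals["PUFA"]
        tot_mean = DESCRIPTIVE[frac_name]["TotalFA"]["calibration"][0]
        member_mean = sum(DESCRIPTIVE[frac_name][m]["calibration"][0]
                          for m in FATTY_ACIDS)
        rem_mean = max(tot_mean - member_mean, 0.0)
        tot_cv = DESCRIPTIVE[frac_name]["TotalFA"]["calibration"][4]
        rho = config.rho_neutral if frac_name == "total" else config.rho_phospholipid
        remainder = _copula_lognormal(rng, z_latent, rem_mean,
                                      rem_mean * tot_cv / 100.0, rho)
        frac_vals["TotalFA"] = group_sum + remainder

    rows = []
    for frac_name, frac_vals in (("phospholipid", phospho), ("total", total)):
        for name, vals in frac_vals.items():
            for sid, v in zip(sample_ids, vals):
                rows.append((sid, frac_name, name, float(v)))
    return pd.DataFrame(rows, columns=["sample_id", "fraction", "analyte",
                                       "value_mg_per_100g"])


# ---------------------------------------------------------------------------
# Band library

#: Canonical lipid band centres (nm): C-H first overtone around 1700-1770,
#: cis-unsaturation-sensitive bands, and the C-H combination region with the
#: 2310/2348 nm peaks characteristic of lipid absorption.
_CH_OVERTONE = ((1725.0, 25.0), (1765.0, 22.0))
_CH_COMBINATION = ((2310.0, 22.0), (2348.0, 20.0), (2280.0, 30.0))
_UNSAT = ((2145.0, 30.0), (1680.0, 25.0))


def default_band_library(
    grid: WavelengthGrid | None = None,
    coeff_scale: float = 2.0e-5,
) -> dict[str, list[tuple[float, float, float]]]:
    """Stylized Gaussian band assignments per fatty acid.

    Every acid shares the main C-H overtone and combination bands (that
    shared absorption is what makes minor analytes hard to calibrate);
    unsaturated acids add cis-double-bond bands with weight growing with the
    number of double bonds, and each acid gets a deterministic, analyte-
    specific modulation of the shared weights plus one weak satellite band
    so the mixing matrix has full column rank.

    ``coeff_scale`` sets the absorbance contributed per mg/100 g.  The
    default makes the lipid peaks subtle — roughly 0.05 AU at the mean total
    fatty-acid load, with the fattest samples approaching 1.4 AU at the
    combination band — as seen in freeze-dried meat, where the scattering
    baseline dominates and chemical peaks only emerge after pretreatment.

    Returns ``{analyte: [(center_nm, width_nm, coeff_per_mg_100g), ...]}``.
    """
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(20210421)  # fixed: band library is a constant
    unsaturation = {
        "12:0": 0, "14:0": 0, "16:0": 0, "16:0ald": 0, "18:0": 0,
        "18:0ald": 0, "16:1": 1, "18:1t9": 1, "18:1c9": 1, "18:1c11": 1,
        "20:1": 1, "18:2n-6": 2, "9c11tCLA": 2, "18:3n-3": 3, "20:3n-6": 3,
        "20:4n-6": 4, "20:5n-3": 5, "22:4n-6": 4, "22:5n-3": 5, "22:6n-3": 6,
    }
    library: dict[str, list[tuple[float, float, float]]] = {}
    for name in FATTY_ACIDS:
        bands: list[tuple[float, float, float]] = []
        mod = 1.0 + 0.25 * rng.standard_normal(len(_CH_OVERTONE) + len(_CH_COMBINATION))
        i = 0
        for center, width in _CH_OVERTONE + _CH_COMBINATION:
            bands.append((center, width, coeff_scale * abs(mod[i])))
            i += 1
        du = unsaturation[name]
        if du:
            for center, width in _UNSAT:
                bands.append((center, width, coeff_scale * 0.3 * du))
        satellite = float(rng.uniform(1550.0, 2450.0))
        bands.append((satellite, 18.0, coeff_scale * 0.4))
        for center, _, _ in bands:
            if not (grid.start_nm <= center <= grid.end_nm):
                raise ConfigurationError(
                    f"band centre {center} nm outside the wavelength grid"
                )
        library[name] = bands
    return library


def baseline_shape(grid: WavelengthGrid) -> np.ndarray:
    """Monotone scattering baseline: ~0.4 below 1600 nm rising to ~1.0 at 2500 nm."""
    lam = grid.wavelengths()
    return 0.4 + 0.65 / (1.0 + np.exp(-(lam - 2000.0) / 200.0))


def mix_spectrum(
    concentrations: dict[str, float],
    bands: dict[str, list[tuple[float, float, float]]],
    grid: WavelengthGrid,
) -> np.ndarray:
    """Deterministic Beer-Lambert mixing: baseline + sum of Gaussian bands."""
    lam = grid.wavelengths()
    x = baseline_shape(grid).copy()
    for name, c in concentrations.items():
        if c == 0:
            continue
        for center, width, coeff in bands[name]:
            x += c * coeff * np.exp(-0.5 * ((lam - center) / width) ** 2)
    return x


def simulate_spectra(
    reference: pd.DataFrame,
    config: SimulationConfig,
    bands: dict[str, list[tuple[float, float, float]]] | None = None,
    grid: WavelengthGrid | None = None,
    n_scans: int = 1,
) -> list[Spectrum]:
    """Generate log(1/R) scans for every sample in *reference*.

    The chemical signal uses the total-fraction concentrations of the 20
    individual fatty acids (group sums are not mixed in again).  Scatter
    (gain, offset, tilt) is drawn once per sample; white noise is drawn per
    scan so replicate averaging has something to average.
    """
    grid = grid or DEFAULT_GRID
    bands = bands or default_band_library(grid)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tot = reference[(reference["fraction"] == "total")
                    & (reference["analyte"].isin(FATTY_ACIDS))]
    wide = tot.pivot(index="sample_id", columns="analyte",
                     values="value_mg_per_100g")
    lam_norm = grid.normalized()
    spectra: list[Spectrum] = []
    for sid, row in wide.iterrows():
        clean = mix_spectrum(row.to_dict(), bands, grid)
        gain = 1.0 + config.scatter_gain_sd * rng.standard_normal()
        offset = config.scatter_offset_sd * rng.standard_normal()
        tilt = config.baseline_tilt_sd * rng.standard_normal()
        base = gain * clean + offset + tilt * lam_norm
        for scan in range(n_scans):
            noise = config.noise_sd * rng.standard_normal(grid.n_points)
            spectra.append(Spectrum(
                sample_id=str(sid),
                scan_index=scan if n_scans > 1 else None,
                absorbance=base + noise,
                grid=grid,
            ))
    return spectra


def generate_dataset(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a complete synthetic dataset to *out_dir*.

    Emits ``spectra.csv`` (two scans per sample, to exercise replicate
    averaging), ``chemistry.csv`` (long-format reference table) and
    ``manifest.json`` recording the generative parameters.  Deterministic
    given the config seed.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = simulate_concentrations(config)
    spectra = simulate_spectra(reference, config, n_scans=2)
    spectra_path = out / "spectra.csv"
    chem_path = out / "chemistry.csv"
    manifest_path = out / "manifest.json"
    write_spectra(spectra_path, spectra)
    write_reference(chem_path, reference)
    with open(manifest_path, "w") as fh:
        json.dump({"config": asdict(config), "n_scans": 2,
                   "grid": {"start_nm": DEFAULT_GRID.start_nm,
                            "step_nm": DEFAULT_GRID.step_nm,
                            "n_points": DEFAULT_GRID.n_points}},
                  fh, indent=2)
    return {"spectra": str(spectra_path), "chemistry": str(chem_path),
            "manifest": str(manifest_path)}
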