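"""Model/results interface for one analyte calibration.

:class:`NIRSCalibration` is built from a :class:`~nirspec_fa.spectra_io.Dataset`
(spectra + one analyte's reference concentrations) and a handful of
hyper-parameters; :meth:`NIRSCalibration.fit` runs the full workflow —
random calibration/validation split, pretreatment-chain fitting on the
calibration half only, NIPALS PLS fit, Hotelling outlier removal with one
refit, optional coefficient-based wavelength selection — and returns a
:class:`NIRSCalibrationResults` carrying the estimates, validation figures
of merit, diagnostics, ``summary()`` table, prediction and plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import metrics, pls
from .errors import NirspecError
from .preprocess import EMSC, MSC, PretreatmentChain, parse_chain
from .spectra_io import Dataset, Spectrum, WavelengthGrid


class NIRSCalibration:
    """NIR calibration model for one analyte in one lipid fraction.

    Parameters
    ----------
    dataset : Dataset
        Aligned spectra and reference concentrations.
    chain : str
        Pretreatment chain specification, e.g. ``"Offset|Area|SNV+D|SG-1-2-3"``.
    n_factors : int or "auto"
        PLS factor count; ``"auto"`` selects by venetian-blind
        cross-validation (smallest statistically indistinguishable model).
    split_threshold : float
        Per-sample probability of assignment to the calibration set
        (a uniform draw below the threshold calibrates the sample).
    outlier_threshold : float
        Hotelling H cutoff; flagged calibration samples are dropped once and
        the model refitted.
    coef_quantile : float or None
        If set, wavelengths whose |coefficient| falls below this quantile
        are dropped and the reduced model kept only when cross-validated R²
        improves.
    """

    def __init__(
        self,
        dataset: Dataset,
        chain: str = "None",
        n_factors: int | str = "auto",
        split_threshold: float = 0.67,
        outlier_threshold: float = 10.0,
        seed: int = 0,
        f_max: int = 15,
        cv_folds: int = 10,
        coef_quantile: float | None = None,
    ):
        if not 0 < split_threshold < 1:
            raise ValueError("split_threshold must be in (0, 1)")
        if n_factors != "auto" and int(n_factors) < 1:
            raise ValueError("n_factors must be >= 1 or 'auto'")
        if coef_quantile is not None and not 0 <= coef_quantile < 1:
            raise ValueError("coef_quantile must lie in [0, 1)")
        self.dataset = dataset
        self.chain_spec = chain
        self.n_factors = n_factors
        self.split_threshold = split_threshold
        self.outlier_threshold = outlier_threshold
        self.seed = seed
        self.f_max = f_max
        self.cv_folds = cv_folds
        self.coef_quantile = coef_quantile

    @classmethod
    def from_files(
        cls,
        spectra_path,
        chemistry_path,
        fraction: str,
        analyte: str,
        grid: WavelengthGrid | None = None,
        **kwargs,
    ) -> "NIRSCalibration":
        """Build the model from the CSV carriers (scans are replicate-averaged)."""
        from .spectra_io import assemble_dataset, average_replicates, read_reference, read_spectra

        spectra = average_replicates(read_spectra(spectra_path, grid))
        reference = read_reference(chemistry_path)
        dataset = assemble_dataset(spectra, reference, fraction, analyte, grid)
        return cls(dataset, **kwargs)

    def fit(self) -> "NIRSCalibrationResults":
        from .pipeline import random_split, select_wavelengths

        ds = self.dataset
        cal_idx, val_idx = random_split(
            np.arange(ds.n_samples), self.split_threshold, self.seed
        )
        X_cal, y_cal = ds.X[cal_idx], ds.y[cal_idx]
        X_val, y_val = ds.X[val_idx], ds.y[val_idx]

        chain = parse_chain(self.chain_spec)
        Xc = chain.fit_transform(X_cal, ds.grid)
        Xv = chain.transform(X_val, ds.grid)

        if self.n_factors == "auto":
            f_cap = min(self.f_max, X_cal.shape[0] - 2, ds.grid.n_points)
            F = pls.select_factors(Xc, y_cal, f_cap, folds=self.cv_folds,
                                   seed=self.seed)
        else:
            F = int(self.n_factors)

        mask = np.ones(ds.grid.n_points, dtype=bool)
        if self.coef_quantile is not None and self.coef_quantile > 0:
            full_model = pls.fit_pls(Xc, y_cal, F)
            cand = select_wavelengths(full_model, self.coef_quantile)
            r2_full = pls.cross_val_r2(Xc, y_cal, F, folds=self.cv_folds,
                                       seed=self.seed)[F - 1]
            r2_masked = pls.cross_val_r2(Xc[:, cand], y_cal, F,
                                         folds=self.cv_folds,
                                         seed=self.seed)[F - 1]
            if r2_masked > r2_full:
                mask = cand

        model, removed_local = pls.remove_outliers_refit(
            Xc[:, mask], y_cal, F, threshold=self.outlier_threshold
        )
        removed_idx = cal_idx[removed_local]
        kept_local = np.setdiff1d(np.arange(len(cal_idx)), removed_local)

        y_cal_kept = y_cal[kept_local]
        pred_cal = model.predict(Xc[kept_local][:, mask])
        pred_val = model.predict(Xv[:, mask])

        F_eff = model.n_factors
        sec_val = metrics.sec(y_cal_kept, pred_cal, F_eff)
        r2c = metrics.r_squared(y_cal_kept, pred_cal)
        sep_val, rmsep = metrics.sep(y_val, pred_val)
        r2p = metrics.r_squared(y_val, pred_val)
        sd_validation = float(np.std(y_val, ddof=1))
        rpd_val = metrics.rpd(sd_validation, sep_val) if sep_val > 0 else float("inf")
        cons = metrics.consistency(sec_val, sep_val) if sep_val > 0 else float("nan")

        return NIRSCalibrationResults(
            model=self,
            chain=chain,
            wavelength_mask=mask,
            pls_model=model,
            n_factors=F_eff,
            calibration_idx=cal_idx,
            validation_idx=val_idx,
            removed_idx=removed_idx,
            y_validation=y_val,
            pred_validation=pred_val,
            y_calibration=y_cal_kept,
            pred_calibration=pred_cal,
            sec=sec_val,
            r2c=r2c,
            sep=sep_val,
            rmsep=rmsep,
            r2p=r2p,
            sd_validation=sd_validation,
            rpd=rpd_val,
            consistency=cons,
        )


@dataclass
class NIRSCalibrationResults:
    """Fitted calibration with its validation figures of merit."""

    model: NIRSCalibration
    chain: PretreatmentChain
    wavelength_mask: np.ndarray
    pls_model: pls.PLSModel
    n_factors: int
    calibration_idx: np.ndarray
    validation_idx: np.ndarray
    removed_idx: np.ndarray
    y_validation: np.ndarray
    pred_validation: np.ndarray
    y_calibration: np.ndarray
    pred_calibration: np.ndarray
    sec: float
    r2c: float
    sep: float
    rmsep: float
    r2p: float
    sd_validation: float
    rpd: float
    consistency: float
    extras: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    @property
    def n_calibration(self) -> int:
        """Calibration samples retained after outlier removal."""
        return len(self.calibration_idx) - len(self.removed_idx)

    @property
    def n_validation(self) -> int:
        return len(self.validation_idx)

    @property
    def removed_ids(self) -> list[str]:
        ids = self.model.dataset.sample_ids
        return [ids[i] for i in self.removed_idx]

    @property
    def rpd_class(self) -> str:
        return metrics.classify_rpd(self.rpd)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the full wavelength grid (zeros where
        wavelengths were dropped by selection)."""
        b = np.zeros(self.model.dataset.grid.n_points)
        b[self.wavelength_mask] = self.pls_model.coef
        return b

    def report_row(self) -> dict:
        ds = self.model.dataset
        return metrics.report_row(
            ds.analyte, self.n_calibration, self.sec, self.r2c,
            self.sep, self.r2p, self.rpd, self.consistency,
        )

    # -- prediction on new data ---------------------------------------------

    def predict(self, spectra) -> np.ndarray:
        """Predict concentrations for new spectra (Spectrum list or array)."""
        grid = self.model.dataset.grid
        if isinstance(spectra, np.ndarray):
            X = np.atleast_2d(spectra)
        else:
            X = np.vstack([s.absorbance for s in spectra])
        Xt = self.chain.transform(X, grid)
        return self.pls_model.predict(Xt[:, self.wavelength_mask])

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "NIR calibration results",
            "=" * 58,
            f"analyte:             {ds.analyte} ({ds.fraction} fraction)",
            f"pretreatment chain:  {self.chain.spec()}",
            f"PLS factors:         {self.n_factors}",
            f"wavelengths used:    {int(self.wavelength_mask.sum())} / "
            f"{ds.grid.n_points}",
            f"calibration samples: {self.n_calibration} "
            f"({len(self.removed_idx)} outliers removed, H > "
            f"{self.model.outlier_threshold:g})",
            f"validation samples:  {self.n_validation}",
            "-" * 58,
            f"{'SEC':>12} {'R2c':>8} {'SEP':>12} {'R2p':>8} {'RPD':>6} "
            f"{'Consistency':>12}",
            f"{self.sec:>12.4g} {self.r2c:>8.3f} {self.sep:>12.4g} "
            f"{self.r2p:>8.3f} {self.rpd:>6.2f} {self.consistency:>11.2f}%",
            "-" * 58,
            f"RMSEP: {self.rmsep:.4g}   validation SD: {self.sd_validation:.4g}"
            f"   class: {self.rpd_class}",
        ]
        return "\n".join(lines)

    def plot_coefficients(self, ax=None):
        """Regression coefficient per wavelength (the model's fingerprint)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        grid = self.model.dataset.grid
        ax.plot(grid.wavelengths(), self.coefficients, lw=0.8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("regression coefficient")
        ax.set_title(f"{self.model.dataset.analyte} "
                     f"({self.model.dataset.fraction})")
        return ax

    def plot_validation(self, ax=None):
        """Reference vs predicted scatter for the validation set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(self.y_validation, self.pred_validation, s=12, alpha=0.7)
        lim = [min(self.y_validation.min(), self.pred_validation.min()),
               max(self.y_validation.max(), self.pred_validation.max())]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("reference (mg/100 g)")
        ax.set_ylabel("predicted (mg/100 g)")
        ax.set_title(f"R²p = {self.r2p:.2f}, RPD = {self.rpd:.2f}")
        return ax

    # -- serialization --------------------------------------------------------

    def save(self, path) -> None:
        """Serialize everything needed to predict on new spectra."""
        ds = self.model.dataset
        chain_state = []
        for step in self.chain.steps:
            if isinstance(step, (MSC, EMSC)) and step.reference is not None:
                chain_state.append(step.reference.tolist())
            else:
                chain_state.append(None)
        doc = {
            "grid": {"start_nm": ds.grid.start_nm, "step_nm": ds.grid.step_nm,
                     "n_points": ds.grid.n_points},
            "fraction": ds.fraction,
            "analyte": ds.analyte,
            "chain_spec": self.chain.spec(),
            "chain_state": chain_state,
            "wavelength_mask": np.nonzero(self.wavelength_mask)[0].tolist(),
            "pls": self.pls_model.to_dict(),
            "figures_of_merit": self.report_row(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def load_predictor(path):
    """Load a saved calibration as a ``predict(X) -> y`` closure.

    Returns ``(predict_fn, info_dict)``; the closure applies the stored
    pretreatment chain (with its frozen MSC/EMSC references), wavelength
    mask and PLS coefficients.
    """
    with open(path) as fh:
        doc = json.load(fh)
    grid = WavelengthGrid(**doc["grid"])
    chain = parse_chain(doc["chain_spec"])
    if len(doc["chain_state"]) != len(chain.steps):
        raise NirspecError("saved chain state does not match chain spec")
    for step, state in zip(chain.steps, doc["chain_state"]):
        if isinstance(step, (MSC, EMSC)):
            if state is None:
                raise NirspecError("missing fitted reference for scatter step")
            step.reference = np.asarray(state, dtype=float)
    chain.fitted = True
    mask = np.zeros(grid.n_points, dtype=bool)
    mask[np.asarray(doc["wavelength_mask"], dtype=int)] = True
    model = pls.PLSModel.from_dict(doc["pls"])

    def predict_fn(spectra):
        if isinstance(spectra, np.ndarray):
            X = np.atleast_2d(spectra)
        else:
            X = np.vstack([s.absorbance for s in spectra])
        Xt = chain.transform(X, grid)
        return model.predict(Xt[:, mask])

    return predict_fn, doc
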