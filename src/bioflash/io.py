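"""File formats, configuration, and batch pipeline orchestration.

Interchange is plain delimited text (comma by default, tab accepted) with
explicit headers: photon-count records as ``time_s,counts`` (or a single
counts column with the bin width taken from the configuration), spectra as
``wavelength_nm,intensity[,background]``.  The pipeline writes per-flash,
per-record, per-spectrum, and statistics CSVs plus a machine-readable run
manifest (configuration echo, package version, input checksums).  All
randomness flows from the single configured seed, and identical inputs,
configuration, and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flash import InvalidInputError, PhotonTimeSeries, analyze_record
from .spectra import EmissionSpectrum, SpectrumError, summarize_spectrum
from .stats import geometric_mean_ci

__all__ = [
    "RunConfig",
    "ParseError",
    "read_timeseries",
    "write_timeseries",
    "read_spectrum",
    "write_spectrum",
    "run_pipeline",
]

logger = logging.getLogger("bioflash")

FLOAT_FORMAT = "%.10g"

KINETIC_COLUMNS = (
    "rise_time_ms",
    "max_intensity_photons_per_s",
    "efold_time_ms",
    "decay90_time_ms",
    "duration_ms",
    "integrated_photons",
)


class ParseError(InvalidInputError):
    """A delimited-text input failed validation; the message names the row."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; unknown keys are rejected at load time."""

    bin_width_s: float = 0.010
    threshold_sigma: float = 3.0
    min_gap_bins: int = 5
    calibration: float = 1.0
    qe_correction: float = 1.0
    sg_window: int = 25
    sg_degree: int = 2
    sg_passes: int = 1
    analysis_range_nm: tuple[float, float] = (350.0, 700.0)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bin_width_s > 0:
            raise InvalidInputError("bin_width_s must be positive")
        if not self.threshold_sigma > 0:
            raise InvalidInputError("threshold_sigma must be positive")
        if self.min_gap_bins < 0:
            raise InvalidInputError("min_gap_bins must be non-negative")
        if not (self.calibration > 0 and self.qe_correction > 0):
            raise InvalidInputError("calibration factors must be positive")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_degree:
            raise InvalidInputError("sg_window must be odd and > sg_degree")
        if self.sg_passes < 0:
            raise InvalidInputError("sg_passes must be non-negative")
        lo, hi = self.analysis_range_nm
        if not lo < hi:
            raise InvalidInputError("analysis_range_nm must be (low, high)")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "analysis_range_nm" in kwargs:
            kwargs["analysis_range_nm"] = tuple(kwargs["analysis_range_nm"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise InvalidInputError("config file must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_range_nm"] = list(self.analysis_range_nm)
        return d


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, tolerating an optional header."""
    with open(path) as fh:
        first_line = fh.readline()
    sep = "\t" if "\t" in first_line else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=None)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: cannot parse ({exc})") from exc
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def read_timeseries(
    path: str | Path,
    bin_width: float | None = None,
    calibration: float = 1.0,
    qe_correction: float = 1.0,
) -> PhotonTimeSeries:
    """Read a photon-count record from delimited text.

    Two columns are interpreted as (time_s, counts); the time column must be
    monotone with uniform spacing (1% tolerance).  A single column is counts
    with ``bin_width`` supplied from configuration.  Counts must be
    non-negative integers; violations are reported with their row number.
    """
    df = _read_table(path)
    if df.shape[1] == 1:
        counts = df.iloc[:, 0].to_numpy()
        if bin_width is None:
            raise ParseError(f"{path}: counts-only file requires a bin width")
        t0 = 0.0
    elif df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy()
        counts = df.iloc[:, 1].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 2
            raise ParseError(f"{path}: time not strictly increasing at row {row}")
        width = float(np.median(dt))
        if np.any(np.abs(dt - width) > 0.01 * width):
            row = int(np.argmax(np.abs(dt - width) > 0.01 * width)) + 2
            raise ParseError(f"{path}: non-uniform bin width at row {row}")
        if bin_width is not None and abs(width - bin_width) > 0.01 * bin_width:
            raise ParseError(
                f"{path}: file bin width {width:g}s conflicts with configured "
                f"{bin_width:g}s"
            )
        bin_width = width
        t0 = float(t[0]) - 0.5 * width
    else:
        raise ParseError(f"{path}: expected one or two columns")

    bad = np.flatnonzero((counts < 0) | (np.abs(counts - np.round(counts)) > 1e-9))
    if bad.size:
        raise ParseError(
            f"{path}: count at row {int(bad[0]) + 1} is negative or non-integer"
        )
    return PhotonTimeSeries(
        counts=np.round(counts),
        bin_width=float(bin_width),
        t0=t0,
        calibration=calibration,
        qe_correction=qe_correction,
    )


def write_timeseries(series: PhotonTimeSeries, path: str | Path) -> None:
    """Write a record as ``time_s,counts`` (counts rounded to integers)."""
    df = pd.DataFrame(
        {
            "time_s": series.times,
            "counts": np.round(series.counts).astype(np.int64),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_spectrum(path: str | Path) -> EmissionSpectrum:
    """Read ``wavelength_nm,intensity[,background]`` from delimited text."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least two columns")
    wl = df.iloc[:, 0].to_numpy()
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2
        raise ParseError(
            f"{path}: wavelengths not strictly increasing at row {row}"
        )
    background = df.iloc[:, 2].to_numpy() if df.shape[1] >= 3 else None
    try:
        return EmissionSpectrum(
            wavelengths=wl,
            intensities=df.iloc[:, 1].to_numpy(),
            background=background,
        )
    except SpectrumError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectrum(spec: EmissionSpectrum, path: str | Path) -> None:
    data = {"wavelength_nm": spec.wavelengths, "intensity": spec.intensities}
    if spec.background is not None:
        data["background"] = spec.background
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    timeseries: Sequence[str | Path] = (),
    spectra: Sequence[str | Path] = (),
) -> dict[str, pd.DataFrame]:
    """Batch analysis of flash records and spectra.

    Writes ``flashes.csv`` (per-flash kinetics), ``records.csv`` (flash
    counts), ``spectra.csv`` (peak/FWHM/SNR summaries), ``stats.csv``
    (geometric means with back-transformed confidence limits per kinetic
    parameter, truncated flashes excluded), and ``manifest.json``.  A failing
    input is logged and reported in the manifest; the batch continues.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts_paths = sorted(Path(p) for p in timeseries)
    sp_paths = sorted(Path(p) for p in spectra)

    flash_rows: list[dict] = []
    record_rows: list[dict] = []
    spectrum_rows: list[dict] = []
    failures: list[dict] = []

    for path in ts_paths:
        record_id = path.stem
        try:
            series = read_timeseries(
                path,
                bin_width=config.bin_width_s,
                calibration=config.calibration,
                qe_correction=config.qe_correction,
            )
            summary = analyze_record(
                series,
                threshold_sigma=config.threshold_sigma,
                min_gap_bins=config.min_gap_bins,
            )
        except InvalidInputError as exc:
            logger.error("record %s failed: %s", record_id, exc)
            failures.append({"input": str(path), "error": str(exc)})
            continue
        logger.info(
            "record %s: %d flashes (%d skipped)",
            record_id,
            summary.n_flashes,
            len(summary.skipped),
        )
        record_rows.append({"record_id": record_id, "n_flashes": summary.n_flashes})
        for i, fk in enumerate(summary.flashes):
            flash_rows.append(
                {
                    "record_id": record_id,
                    "flash_index": i,
                    "rise_time_ms": fk.rise_time_ms,
                    "max_intensity_photons_per_s": fk.max_intensity_photons_per_s,
                    "efold_time_ms": fk.efold_time_ms,
                    "decay90_time_ms": fk.decay90_time_ms,
                    "duration_ms": fk.duration_ms,
                    "integrated_photons": fk.integrated_photons,
                    "truncated": fk.truncated,
                }
            )
        for i, reason in summary.skipped:
            logger.warning("record %s flash %d skipped: %s", record_id, i, reason)
            failures.append(
                {"input": str(path), "error": f"flash {i} skipped: {reason}"}
            )

    for path in sp_paths:
        spectrum_id = path.stem
        try:
            spec = read_spectrum(path)
            summ = summarize_spectrum(
                spec,
                window=config.sg_window,
                degree=config.sg_degree,
                passes=config.sg_passes,
                window_nm=config.analysis_range_nm,
            )
        except (InvalidInputError, SpectrumError) as exc:
            logger.error("spectrum %s failed: %s", spectrum_id, exc)
            failures.append({"input": str(path), "error": str(exc)})
            continue
        spectrum_rows.append(
            {
                "spectrum_id": spectrum_id,
                "peak_wavelength_nm": summ.peak_wavelength_nm,
                "fwhm_nm": summ.fwhm_nm,
                "snr": summ.snr,
                "passes": summ.smoothed_passes,
            }
        )

    flashes_df = pd.DataFrame(
        flash_rows,
        columns=["record_id", "flash_index", *KINETIC_COLUMNS, "truncated"],
    )
    records_df = pd.DataFrame(record_rows, columns=["record_id", "n_flashes"])
    spectra_df = pd.DataFrame(
        spectrum_rows,
        columns=["spectrum_id", "peak_wavelength_nm", "fwhm_nm", "snr", "passes"],
    )

    stats_rows: list[dict] = []
    if not flashes_df.empty:
        usable = flashes_df[~flashes_df["truncated"]]
        for col in KINETIC_COLUMNS:
            values = usable[col].to_numpy()
            values = values[values > 0]
            if values.size >= 2:
                g = geometric_mean_ci(values, alpha=config.alpha)
                stats_rows.append(
                    {
                        "parameter": col,
                        "geometric_mean": g.geometric_mean,
                        "ci_low": g.ci_low,
                        "ci_high": g.ci_high,
                        "n": g.n,
                    }
                )
    stats_df = pd.DataFrame(
        stats_rows, columns=["parameter", "geometric_mean", "ci_low", "ci_high", "n"]
    )

    tables = {
        "flashes": flashes_df,
        "records": records_df,
        "spectra": spectra_df,
        "stats": stats_df,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=FLOAT_FORMAT)

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "inputs": {
            str(p): _sha256(p) for p in [*ts_paths, *sp_paths] if p.exists()
        },
        "outputs": sorted(f"{name}.csv" for name in tables),
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tables
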