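"""Readers, writers and configuration for the screening pipeline.

Spectra travel as two-column (m/z, intensity) tab-separated text with
``#``-prefixed header lines, or as mzML.  mzML reading goes through
pyteomics; writing uses a minimal single-spectrum mzML emitter (64-bit,
uncompressed, base64) that pyteomics reads back bit-exactly.
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
import xml.sax.saxutils as _sax
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import CatalogError, ConfigError, SpectrumFormatError
from .screen import ScreenParams, ScreenResult
from .signal import Spectrum
from .simulate import SimulationConfig

__all__ = [
    "read_spectrum",
    "write_spectrum_tsv",
    "write_spectrum_mzml",
    "read_catalog_file",
    "write_peaks_csv",
    "screen_result_to_dict",
    "write_screen_result_json",
    "write_cohort",
    "PipelineConfig",
]


# ---------------------------------------------------------------- spectra


def _read_tsv_spectrum(path: Path) -> Spectrum:
    mz, inten, meta = [], [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row: {line!r}") from exc
    if not mz:
        raise SpectrumFormatError(f"{path}: empty spectrum file")
    mz_arr = np.asarray(mz)
    inten_arr = np.asarray(inten)
    if not np.all(np.diff(mz_arr) > 0):
        warnings.warn(f"{path}: m/z not ascending; sorting", stacklevel=2)
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, inten_arr = mz_arr[order], inten_arr[order]
    return Spectrum(mz=mz_arr, intensity=inten_arr, metadata=meta)


def _decode_binary_array(elem, ns: str) -> np.ndarray:
    accessions = {cv.get("accession") for cv in elem.iter(f"{ns}cvParam")}
    dtype = "<f8" if "MS:1000523" in accessions else "<f4"
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml_spectrum(path: Path) -> Spectrum:
    """First spectrum of an mzML file (64/32-bit float arrays, plain or zlib)."""
    import xml.etree.ElementTree as ET

    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectrumFormatError(f"{path}: not well-formed mzML: {exc}") from exc
    ns = root.tag.partition("}")[0] + "}" if root.tag.startswith("{") else ""
    for spectrum in root.iter(f"{ns}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            if "MS:1000514" in accessions:
                arrays["mz"] = _decode_binary_array(bda, ns)
            elif "MS:1000515" in accessions:
                arrays["intensity"] = _decode_binary_array(bda, ns)
        if "mz" in arrays and "intensity" in arrays:
            return Spectrum(
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                metadata={"source": str(path), "id": spectrum.get("id", "")},
            )
    raise SpectrumFormatError(f"{path}: mzML file holds no usable MS1 spectrum")


def read_spectrum(path: str | Path, format: str = "auto") -> Spectrum:
    """Read a spectrum from two-column text or mzML (first spectrum)."""
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    if format == "auto":
        if path.suffix.lower() == ".mzml":
            format = "mzml"
        else:
            head = path.read_bytes()[:512].lstrip()
            format = "mzml" if head.startswith(b"<?xml") or head.startswith(b"<mzML") else "tsv"
    if format == "tsv":
        return _read_tsv_spectrum(path)
    if format == "mzml":
        return _read_mzml_spectrum(path)
    raise SpectrumFormatError(f"unknown spectrum format {format!r}")


def write_spectrum_tsv(spec: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in spec.metadata.items():
            fh.write(f"# {key}: {val}\n")
        for m, i in zip(spec.mz, spec.intensity):
            fh.write(f"{m:.17g}\t{i:.17g}\n")


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription><fileContent>
    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
  </fileContent></fileDescription>
  <softwareList count="1"><software id="ttrscreen" version="0.1.0"/></softwareList>
  <instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>
  <dataProcessingList count="1"><dataProcessing id="DP1">
    <processingMethod order="1" softwareRef="ttrscreen"/>
  </dataProcessing></dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="1" defaultDataProcessingRef="DP1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def write_spectrum_mzml(spec: Spectrum, path: str | Path, run_id: str = "run1") -> None:
    """Minimal single-spectrum mzML export (64-bit little-endian, no compression)."""

    def encode(arr: np.ndarray) -> str:
        raw = struct.pack(f"<{len(arr)}d", *arr.astype(float))
        return base64.b64encode(raw).decode("ascii")

    mz_b64, int_b64 = encode(spec.mz), encode(spec.intensity)
    Path(path).write_text(
        _MZML_TEMPLATE.format(
            run_id=_sax.escape(run_id),
            npts=len(spec),
            mz_len=len(mz_b64),
            mz_b64=mz_b64,
            int_len=len(int_b64),
            int_b64=int_b64,
        )
    )


# ------------------------------------------------------------- catalogues


def read_catalog_file(path: str | Path) -> list[str]:
    """Mutation labels from a tab-separated catalogue file.

    Column ``mutation`` is required; other columns (e.g. ``note``) and
    ``#`` comment lines are ignored.  A headerless single-column file is
    accepted as a bare list of labels.
    """
    path = Path(path)
    labels: list[str] = []
    col = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if col is None:
                if "mutation" in parts:
                    col = parts.index("mutation")
                    continue
                col = 0
            if col >= len(parts):
                raise CatalogError(f"{path}: row {line!r} lacks a mutation column")
            labels.append(parts[col])
    if not labels:
        raise CatalogError(f"{path}: no mutations found")
    return labels


# ------------------------------------------------------------ results


def write_peaks_csv(peaks, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("centroid_mz,apex_intensity,fwhm,snr,area\n")
        for p in peaks:
            fh.write(
                f"{p.centroid_mz:.4f},{p.apex_intensity:.6g},{p.fwhm:.4f},"
                f"{p.snr:.4g},{p.area:.6g}\n"
            )


def screen_result_to_dict(result: ScreenResult, name: str | None = None) -> dict:
    def peak_dict(p):
        if p is None:
            return None
        return {
            "centroid_mz": round(p.centroid_mz, 4),
            "apex_intensity": p.apex_intensity,
            "fwhm": round(p.fwhm, 4),
            "snr": round(p.snr, 2),
            "area": p.area,
        }

    out = {
        "status": result.status.value,
        "wt_peak": peak_dict(result.wt_peak),
        "variant_peak": peak_dict(result.variant_peak),
        "measured_shift": (
            None if result.measured_shift is None else round(result.measured_shift, 2)
        ),
        "matches": [
            {"mutation": e.label, "delta_mass": round(e.delta_mass, 2),
             "deviation": round(dev, 2)}
            for e, dev in (result.call.matches if result.call else ())
        ],
        "calibration": (
            None
            if result.calibration is None
            else {
                "slope": result.calibration.slope,
                "offset": result.calibration.offset,
                "rms_residual": result.calibration.rms_residual,
                "n_points": result.calibration.n_points,
            }
        ),
        "n_peaks": len(result.peaks),
    }
    if name is not None:
        out["input"] = name
    return out


def write_screen_result_json(result: ScreenResult, path: str | Path, name=None) -> None:
    Path(path).write_text(json.dumps(screen_result_to_dict(result, name), indent=2) + "\n")


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write simulated spectra as TSV plus a manifest pairing file to truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tgenotype\twt_mass\tvariant_mass\ttrue_shift\t"
                 "miscal_slope\tmiscal_offset\tseed\n")
        for i, (spec, truth) in enumerate(cohort, 1):
            fname = f"sample_{i:03d}_{truth.genotype_label}.tsv"
            write_spectrum_tsv(spec, out_dir / fname)
            shift = "" if truth.true_shift is None else f"{truth.true_shift:.4f}"
            vmass = "" if truth.variant_mass is None else f"{truth.variant_mass:.4f}"
            fh.write(
                f"{fname}\t{truth.genotype_label}\t{truth.wt_mass:.4f}\t{vmass}\t"
                f"{shift}\t{truth.miscal_slope}\t{truth.miscal_offset}\t{truth.seed}\n"
            )
    return manifest


# -------------------------------------------------------------- config


@dataclass
class PipelineConfig:
    """Nested pipeline configuration; every default is valid without a file."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    screen: ScreenParams = field(default_factory=ScreenParams)
    snr_min: float = 5.0
    baseline_window: float = 200.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = cls()
        top_fields = {f.name for f in fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        for section, klass, attr in (
            ("simulation", SimulationConfig, "simulation"),
            ("screen", ScreenParams, "screen"),
        ):
            sub = data.pop(section, None)
            if sub is None:
                continue
            valid = {f.name for f in fields(klass)}
            bad = set(sub) - valid
            if bad:
                raise ConfigError(f"{path}: unknown keys in {section}: {sorted(bad)}")
            setattr(cfg, attr, replace(getattr(cfg, attr), **sub))
        for key, val in data.items():
            setattr(cfg, key, val)
        cfg.simulation.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": asdict(self.simulation),
            "screen": asdict(self.screen),
            "snr_min": self.snr_min,
            "baseline_window": self.baseline_window,
            "seed": self.seed,
            "log_level": self.log_level,
        }
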