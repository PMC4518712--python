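"""Readers, writers and report rendering.

File formats are plain text throughout:

* SE channel files: CSV with columns ``radius_cm,signal``; a YAML manifest
  groups the channels and carries the per-channel metadata (rotor speed,
  loading, meniscus, bottom, noise sigma) and the shared solution
  properties.  Generated datasets also get a ``truth.yaml`` sidecar
  recording the generating parameters and seed.
* MST files: ``# key: value`` header block (labeled_total_nM) followed by a
  ``conc_nM,fnorm`` table.
* ITC files: header block (cell_volume_ul, cell_conc_uM, syringe_conc_uM,
  temperature_K) followed by an ``inj_ul,heat_ucal`` table.
* Reports: a machine-readable TSV plus a human-readable text summary with
  units on every number; field order is fixed so identical inputs and seed
  reproduce identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .equilibria import AssociationScheme
from .isotherms import ITCExperiment, MSTSeries
from .se import SEChannel, SEExperiment, SolutionProperties

__all__ = [
    "write_se_experiment",
    "read_se_experiment",
    "write_mst_series",
    "read_mst_series",
    "write_itc_experiment",
    "read_itc_experiment",
    "write_report",
]

_FLOAT_FMT = "%.17g"


def _write_table(path: Path, header: list[str], columns: list[np.ndarray],
                 meta: dict | None = None) -> None:
    lines = []
    for key, val in (meta or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append(",".join(header))
    for row in zip(*columns):
        lines.append(",".join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def _read_table(path: Path) -> tuple[dict, np.ndarray]:
    meta: dict[str, float] = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val.strip())
            continue
        if not header_seen:
            header_seen = True  # column names line
            continue
        rows.append([float(v) for v in line.split(",")])
    return meta, np.asarray(rows)


def write_se_experiment(
    experiment: SEExperiment,
    outdir,
    seed: int | None = None,
    truth: dict | None = None,
) -> Path:
    """Write channel CSVs + a YAML manifest (and optional truth sidecar).

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    props = experiment.properties
    manifest = {
        "seed": seed,
        "properties": {
            "monomer_mass": float(props.monomer_mass),
            "vbar": float(props.vbar),
            "density": float(props.density),
            "viscosity": float(props.viscosity),
            "molar_signal": float(props.molar_signal),
            "pathlength": float(props.pathlength),
            "temperature": float(props.temperature),
        },
        "scheme_stoichiometries": list(experiment.scheme.stoichiometries),
        "channels": [],
    }
    for i, ch in enumerate(experiment.channels, start=1):
        fname = f"channel_{i:02d}.csv"
        _write_table(outdir / fname, ["radius_cm", "signal"], [ch.radii, ch.signal])
        manifest["channels"].append(
            {
                "file": fname,
                "rotor_speed": float(ch.rotor_speed),
                "loading_signal": float(ch.loading_signal),
                "meniscus": float(ch.meniscus),
                "bottom": float(ch.bottom),
                "noise_sigma": None if ch.noise_sigma is None else float(ch.noise_sigma),
            }
        )
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    if truth is not None:
        (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    return manifest_path


def read_se_experiment(
    manifest_path, scheme_stoich: tuple[int, ...] | None = None,
    kd_placeholder: float = 1e-5,
) -> SEExperiment:
    """Rebuild an SEExperiment from a manifest.

    The association scheme's stoichiometries come from the manifest unless
    overridden; the constants are placeholders to be fitted.
    """
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    props = SolutionProperties(**manifest["properties"])
    channels = []
    for rec in manifest["channels"]:
        _, data = _read_table(manifest_path.parent / rec["file"])
        channels.append(
            SEChannel(
                radii=data[:, 0],
                signal=data[:, 1],
                rotor_speed=rec["rotor_speed"],
                loading_signal=rec["loading_signal"],
                meniscus=rec["meniscus"],
                bottom=rec["bottom"],
                noise_sigma=rec.get("noise_sigma"),
            )
        )
    stoich = tuple(scheme_stoich or manifest["scheme_stoichiometries"])
    scheme = AssociationScheme(stoich, (kd_placeholder,) * (len(stoich) - 1))
    return SEExperiment(tuple(channels), props, scheme)


def write_mst_series(series: MSTSeries, path) -> Path:
    path = Path(path)
    _write_table(
        path,
        ["conc_nM", "fnorm"],
        [series.titrant_total, series.fnorm],
        meta={"labeled_total_nM": _FLOAT_FMT % series.labeled_total},
    )
    return path


def read_mst_series(path) -> MSTSeries:
    meta, data = _read_table(Path(path))
    return MSTSeries(
        titrant_total=data[:, 0],
        labeled_total=meta["labeled_total_nM"],
        fnorm=data[:, 1],
    )


def write_itc_experiment(exp: ITCExperiment, path) -> Path:
    path = Path(path)
    _write_table(
        path,
        ["inj_ul", "heat_ucal"],
        [exp.injection_volumes, exp.heats],
        meta={
            "cell_volume_ul": _FLOAT_FMT % exp.cell_volume,
            "cell_conc_uM": _FLOAT_FMT % exp.cell_conc,
            "syringe_conc_uM": _FLOAT_FMT % exp.syringe_conc,
            "temperature_K": _FLOAT_FMT % exp.temperature,
        },
    )
    return path


def read_itc_experiment(path) -> ITCExperiment:
    meta, data = _read_table(Path(path))
    return ITCExperiment(
        cell_volume=meta["cell_volume_ul"],
        cell_conc=meta["cell_conc_uM"],
        syringe_conc=meta["syringe_conc_uM"],
        injection_volumes=data[:, 0],
        heats=data[:, 1],
        temperature=meta["temperature_K"],
    )


def write_report(results: dict, out_prefix, seed: int | None = None) -> tuple[Path, Path]:
    """Write a fit/audit report as TSV + human-readable text.

    ``results`` maps field name -> (value, unit) or plain value; insertion
    order is preserved, making the output reproducible bit-for-bit for the
    same inputs and seed.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    txt_path = out_prefix.with_suffix(".txt")

    rows = []
    for key, val in results.items():
        if isinstance(val, tuple) and len(val) == 2:
            value, unit = val
        else:
            value, unit = val, ""
        rows.append((key, value, unit))

    tsv_lines = [f"# seed: {seed}", "field\tvalue\tunit"]
    txt_lines = [f"assocfit report (seed: {seed})", "-" * 40]
    for key, value, unit in rows:
        if isinstance(value, float):
            sval = f"{value:.10g}"
        else:
            sval = str(value)
        tsv_lines.append(f"{key}\t{sval}\t{unit}")
        txt_lines.append(f"{key:32s} {sval} {unit}".rstrip())
    tsv_path.write_text("\n".join(tsv_lines) + "\n")
    txt_path.write_text("\n".join(txt_lines) + "\n")
    return tsv_path, txt_path
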