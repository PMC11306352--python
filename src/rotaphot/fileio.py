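"""Plain-text readers and writers for traces, histograms, spectra and conformers.

CSV files carry a header row and comma-separated values; metadata travels
in '#'-prefixed lines holding a single JSON object.  Conformers use
multi-frame XYZ: an atom-count line, a comment line carrying JSON metadata
(label, energy components, any extra keys), then ``Element x y z`` in
Angstrom.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conformers import Conformer, EnergyComponents, _KNOWN_ELEMENTS
from .fret import Spectrum
from .singlet_oxygen import KineticTrace
from .tcspc import DecayHistogram

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_histogram_csv", "read_histogram_csv",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_xyz", "read_xyz",
]


def _write_csv(path, df: pd.DataFrame, metadata: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    metadata: dict = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            payload = line.lstrip("#").strip()
            if payload:
                metadata.update(json.loads(payload))
    df = pd.read_csv(path, comment="#")
    return df, metadata


def write_trace_csv(path, trace: KineticTrace) -> None:
    meta = dict(trace.metadata)
    meta.update(label=trace.label, absorbance_at_excitation=trace.absorbance_at_excitation)
    _write_csv(path, pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities}), meta)


def read_trace_csv(path) -> KineticTrace:
    df, meta = _read_csv(path)
    label = meta.pop("label", "")
    absorbance = meta.pop("absorbance_at_excitation", 0.8)
    return KineticTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(), absorbance, label, meta)


def write_histogram_csv(path, hist: DecayHistogram) -> None:
    cols = {"time_ns": hist.bin_times, "counts": hist.counts}
    if hist.irf_counts is not None:
        cols["irf_counts"] = hist.irf_counts
    _write_csv(path, pd.DataFrame(cols), dict(hist.metadata))


def read_histogram_csv(path) -> DecayHistogram:
    df, meta = _read_csv(path)
    irf = df["irf_counts"].to_numpy() if "irf_counts" in df.columns else None
    return DecayHistogram(df["time_ns"].to_numpy(), df["counts"].to_numpy(), irf, meta)


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    meta = dict(spectrum.metadata)
    meta.update(kind=spectrum.kind, label=spectrum.label)
    _write_csv(path, pd.DataFrame({"wavelength_nm": spectrum.wavelengths, "value": spectrum.values}), meta)


def read_spectrum_csv(path) -> Spectrum:
    df, meta = _read_csv(path)
    kind = meta.pop("kind", "emission")
    label = meta.pop("label", "")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), kind, label, meta)


def write_xyz(path, conformers) -> None:
    """Write conformers as multi-frame XYZ with JSON metadata comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        for c in conformers:
            meta = dict(c.metadata)
            meta["label"] = c.label
            if c.energy is not None:
                meta["energy"] = {
                    "e_gas": c.energy.e_gas,
                    "g_thermo": c.energy.g_thermo,
                    "dg_solv": c.energy.dg_solv,
                    "unit": c.energy.unit,
                }
            fh.write(f"{c.n_atoms}\n")
            fh.write(json.dumps(meta, sort_keys=True) + "\n")
            for el, (x, y, z) in zip(c.elements, c.coordinates):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> list[Conformer]:
    """Parse a multi-frame XYZ file, recovering JSON comment metadata when present.

    Malformed frames raise ``ValueError`` naming the frame and line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"frame {frame}, line {i + 1}: expected an atom count, got {lines[i]!r}")
        if i + 1 + n_atoms >= len(lines) + 1 and n_atoms > 0 and i + 1 + n_atoms > len(lines):
            raise ValueError(f"frame {frame}: truncated file, expected {n_atoms} atom lines")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta: dict = {}
        if comment.strip().startswith("{"):
            try:
                meta = json.loads(comment)
            except json.JSONDecodeError:
                meta = {"comment": comment}
        elif comment.strip():
            meta = {"comment": comment}
        elements, coords = [], []
        for k in range(n_atoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ValueError(f"frame {frame}: truncated frame, expected {n_atoms} atoms")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame}, line {ln + 1}: malformed coordinate line {lines[ln]!r}")
            el = parts[0]
            if el not in _KNOWN_ELEMENTS:
                raise ValueError(f"frame {frame}, line {ln + 1}: unknown element symbol {el!r}")
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise ValueError(f"frame {frame}, line {ln + 1}: malformed coordinate in {lines[ln]!r}")
            elements.append(el)
        label = meta.pop("label", f"frame{frame}")
        energy = None
        if "energy" in meta:
            e = meta.pop("energy")
            energy = EnergyComponents(e["e_gas"], e["g_thermo"], e["dg_solv"], e.get("unit", "kcal/mol"))
        conformers.append(Conformer(elements, np.array(coords), label, energy, meta))
        i += 2 + n_atoms
    return conformers
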