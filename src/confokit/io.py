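"""Plain-text readers/writers for the toolkit's tabular dialects.

Traces: one TSV per run with columns trace, frame, donor, acceptor and,
when ground truth is available, state_id and bleached.
QENS: per-(T, Q) two-column energy/intensity tables (plus a σ column), one
resolution table, and a manifest CSV listing T, Q and file names.
SAS: 3-column whitespace-delimited q/I/σ text (".dat" dialect), q in Å⁻¹.
Melt: CSV with temperature, fluorescence and an optional condition column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qens import QENSSpectrum
from .sas import ScatteringCurve
from .smfret import IntensityTrace
from .thermal import MeltCurve

__all__ = [
    "write_traces", "read_traces", "read_two_column_trace",
    "write_qens_set", "read_qens_set",
    "write_sas_curve", "read_sas_curve",
    "write_melt_curves", "read_melt_curves",
]


# --- smFRET traces ---------------------------------------------------------

def write_traces(traces: list[IntensityTrace], path: str | Path) -> None:
    rows = []
    for ti, tr in enumerate(traces):
        n = len(tr)
        frame = np.arange(n)
        df = pd.DataFrame({"trace": ti, "frame": frame,
                           "donor": tr.donor, "acceptor": tr.acceptor})
        if tr.truth_states is not None:
            df["state_id"] = tr.truth_states
        if tr.truth_bleach_frame is not None:
            df["bleached"] = (frame >= tr.truth_bleach_frame).astype(int)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path, frame_time: float = 0.1) -> list[IntensityTrace]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, g in df.groupby("trace", sort=True):
        g = g.sort_values("frame")
        states = g["state_id"].to_numpy() if "state_id" in g else None
        bleach = None
        if "bleached" in g:
            hit = np.flatnonzero(g["bleached"].to_numpy())
            bleach = int(hit[0]) if hit.size else len(g)
        out.append(IntensityTrace(g["donor"].to_numpy(), g["acceptor"].to_numpy(),
                                  frame_time=frame_time, truth_states=states,
                                  truth_bleach_frame=bleach))
    return out


def read_two_column_trace(path: str | Path, frame_time: float = 0.1) -> IntensityTrace:
    """Plain two-column (donor, acceptor) text importer."""
    arr = np.loadtxt(path)
    return IntensityTrace(arr[:, 0], arr[:, 1], frame_time=frame_time)


# --- QENS ------------------------------------------------------------------

def write_qens_set(spectra: list[QENSSpectrum], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, s in enumerate(spectra):
        name = f"spectrum_{k:03d}.dat"
        np.savetxt(out / name,
                   np.column_stack([s.energy, s.intensity, s.sigma]),
                   header="energy_ueV intensity sigma")
        rows.append({"temperature_K": s.temperature, "q_invA": s.q,
                     "file": name})
    np.savetxt(out / "resolution.dat",
               np.column_stack([spectra[0].energy, spectra[0].resolution]),
               header="energy_ueV intensity")
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def read_qens_set(in_dir: str | Path) -> list[QENSSpectrum]:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    res = np.loadtxt(src / "resolution.dat")
    out = []
    for _, row in manifest.iterrows():
        arr = np.loadtxt(src / row["file"])
        out.append(QENSSpectrum(q=float(row["q_invA"]),
                                temperature=float(row["temperature_K"]),
                                energy=arr[:, 0], intensity=arr[:, 1],
                                sigma=arr[:, 2], resolution=res[:, 1]))
    return out


# --- SAS -------------------------------------------------------------------

def write_sas_curve(curve: ScatteringCurve, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([curve.q, curve.intensity, curve.sigma]),
               header=f"q_invA I sigma  label={curve.label}")


def read_sas_curve(path: str | Path, label: str = "") -> ScatteringCurve:
    arr = np.loadtxt(path)
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], label=label)


# --- melt curves -----------------------------------------------------------

def write_melt_curves(curves: list[MeltCurve], path: str | Path) -> None:
    rows = [pd.DataFrame({"condition": c.label or f"curve{k}",
                          "temperature_C": c.temperature,
                          "fluorescence": c.fluorescence})
            for k, c in enumerate(curves)]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_melt_curves(path: str | Path) -> list[MeltCurve]:
    df = pd.read_csv(path)
    if "condition" not in df:
        df["condition"] = "curve0"
    return [MeltCurve(g["temperature_C"].to_numpy(),
                      g["fluorescence"].to_numpy(), label=str(name))
            for name, g in df.groupby("condition", sort=False)]
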