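"""Plain-text file formats for the synthetic raw data and results.

* Umbrella windows: one two-column text file per window (time_ps,
  distance_A, ``#`` comment headers) plus a tab-separated metadata table
  (file, center, force constant), mirroring common pull-file/WHAM-input
  conventions.
* Ion frames: extended XYZ with element tags N (spermine amine),
  P (phosphate) and NA (sodium); the comment line carries the inter-DNA
  distance and the periodic z length.
* Traces: long-form CSV (trace_id, frame, I_D, I_A, I_A_direct) plus a
  batch metadata JSON (construct, concentrations, replicate).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth.ions import IonFrame
from .synth.traces import FluorescenceTrace
from .synth.umbrella import UmbrellaWindow
from .wham import PMFEstimate

__all__ = [
    "write_window_series",
    "read_window_series",
    "write_ion_frames_xyz",
    "read_ion_frames_xyz",
    "write_traces_csv",
    "read_traces_csv",
    "write_pmf_csv",
]

FLOAT_FMT = "%.6f"


# --- umbrella windows -------------------------------------------------

def write_window_series(windows: list[UmbrellaWindow], outdir: str | Path,
                        prefix: str = "window") -> Path:
    """Write per-window series files and the metadata table.

    Returns the path of the metadata table (``<prefix>_meta.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"{prefix}_{i:03d}.dat"
        t = np.arange(w.n_samples) * w.sample_interval_ps
        with open(outdir / fname, "w") as fh:
            fh.write("# time_ps distance_A\n")
            fh.write(f"# center_A {w.center:.6f}\n")
            fh.write(f"# force_constant_kcal_per_mol_A2 {w.force_constant:.6f}\n")
            for ti, di in zip(t, w.samples):
                fh.write(f"{ti:.1f} {di:.6f}\n")
        rows.append((fname, w.center, w.force_constant, w.sample_interval_ps))
    meta = outdir / f"{prefix}_meta.tsv"
    with open(meta, "w") as fh:
        fh.write("file\tcenter_A\tforce_constant_kcal_per_mol_A2\tsample_interval_ps\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]:.6f}\t{r[2]:.6f}\t{r[3]:.6f}\n")
    return meta


def read_window_series(meta_path: str | Path) -> list[UmbrellaWindow]:
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path, sep="\t")
    windows = []
    for _, row in meta.iterrows():
        data = np.loadtxt(meta_path.parent / row["file"], comments="#")
        windows.append(
            UmbrellaWindow(
                center=float(row["center_A"]),
                force_constant=float(row["force_constant_kcal_per_mol_A2"]),
                samples=np.atleast_2d(data)[:, 1],
                sample_interval_ps=float(row.get("sample_interval_ps", 2.0)),
            )
        )
    return windows


# --- ion frames -------------------------------------------------------

_SPECIES_TAGS = [("N", "amine_xyz"), ("P", "phosphate_xyz"), ("NA", "sodium_xyz")]


def write_ion_frames_xyz(frames: list[IonFrame], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            n = sum(len(getattr(f, attr)) for _, attr in _SPECIES_TAGS)
            fh.write(f"{n}\n")
            fh.write(f"d={f.d:.4f} box_z={f.box_z:.4f}\n")
            for tag, attr in _SPECIES_TAGS:
                for x, y, z in getattr(f, attr):
                    fh.write(f"{tag} {x:.4f} {y:.4f} {z:.4f}\n")


def read_ion_frames_xyz(path: str | Path) -> list[IonFrame]:
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = dict(
                kv.split("=") for kv in fh.readline().split() if "=" in kv
            )
            coords: dict[str, list] = {tag: [] for tag, _ in _SPECIES_TAGS}
            for _ in range(n):
                tag, x, y, z = fh.readline().split()
                coords[tag].append([float(x), float(y), float(z)])
            frames.append(
                IonFrame(
                    d=float(comment["d"]),
                    amine_xyz=np.array(coords["N"]).reshape(-1, 3),
                    phosphate_xyz=np.array(coords["P"]).reshape(-1, 3),
                    sodium_xyz=np.array(coords["NA"]).reshape(-1, 3),
                    box_z=float(comment.get("box_z", 68.0)),
                )
            )
    return frames


# --- fluorescence traces ----------------------------------------------

def write_traces_csv(traces: list[FluorescenceTrace], path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    frames = []
    for tr in traces:
        df = pd.DataFrame({
            "trace_id": tr.trace_id,
            "frame": np.arange(tr.n_frames),
            "I_D": tr.I_D,
            "I_A": tr.I_A,
            "I_A_direct": tr.I_A_direct,
        })
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.3f"
    )
    if meta_path is not None:
        meta = {
            tr.trace_id: {
                "construct": tr.construct,
                "batch": tr.batch,
                "c_spm_mM": tr.c_spm,
                "frame_dt_s": tr.frame_dt,
            }
            for tr in traces
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_traces_csv(path: str | Path,
                    meta_path: str | Path | None = None
                    ) -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    traces = []
    for tid, group in df.groupby("trace_id", sort=False):
        group = group.sort_values("frame")
        m = meta.get(str(tid), {})
        traces.append(
            FluorescenceTrace(
                trace_id=str(tid),
                I_D=group["I_D"].to_numpy(float),
                I_A=group["I_A"].to_numpy(float),
                I_A_direct=group["I_A_direct"].to_numpy(float),
                frame_dt=float(m.get("frame_dt_s", 0.1)),
                construct=str(m.get("construct", "both")),
                batch=str(m.get("batch", "rep1")),
                c_spm=float(m.get("c_spm_mM", float("nan"))),
            )
        )
    return traces


# --- results ----------------------------------------------------------

def write_pmf_csv(est: PMFEstimate, path: str | Path) -> None:
    """PMF profile CSV with a unit-bearing header comment."""
    with open(path, "w") as fh:
        fh.write("# d_A, dG_kcal_per_mol_per_turn, dG_err (pinned to 0 at "
                 f"{est.pin:.2f} A; {est.turns:g} turns per cell)\n")
        est.to_frame().to_csv(fh, index=False, float_format=FLOAT_FMT)
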