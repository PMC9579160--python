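"""Plain-text and TIFF readers/writers for the package's data exchange formats.

Traces are tab-separated text (``time_s``, ``donor``[, ``acceptor``]) with a
config-hash header; datasets carry a JSON manifest with group labels and
ground truth; spot images are single-channel TIFFs with a CSV truth table;
TCSPC histograms and SAXS curves are whitespace-delimited columns with
``#`` comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import ConditionDataset, SpotField, TcspcHistogram, Trace, get_preset
from .saxs import Pofr, SaxsCurve


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def write_trace(path: str | Path, trace: Trace, config_hash: str = "") -> None:
    path = Path(path)
    cols = {"time_s": trace.time, "donor": trace.donor}
    if trace.acceptor is not None:
        cols["acceptor"] = trace.acceptor
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# smlight trace config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_trace(path: str | Path) -> Trace:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time_s" not in df or "donor" not in df:
        raise ValueError(f"{path}: expected columns time_s, donor[, acceptor]")
    return Trace(
        time=df["time_s"].to_numpy(),
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy() if "acceptor" in df else None,
    )


def write_dataset(directory: str | Path, dataset: ConditionDataset) -> None:
    """One trace file per molecule plus a JSON manifest with truth and groups."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trace_files = []
    for i, tr in enumerate(dataset.traces):
        name = f"trace_{i:05d}.tsv"
        write_trace(directory / name, tr)
        trace_files.append(name)
    manifest = {
        "preset": dataset.preset.name,
        "kind": dataset.kind,
        "seed": dataset.seed,
        "n_molecules": dataset.n_molecules,
        "group_labels": list(map(str, dataset.group_labels)),
        "traces": trace_files,
        "truth": json.loads(dataset.truth.to_json(orient="records")),
        "joint_cells": list(dataset.preset.joint_cells)
        if dataset.preset.joint_cells is not None else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(directory: str | Path) -> ConditionDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    traces = [read_trace(directory / name) for name in manifest["traces"]]
    return ConditionDataset(
        preset=get_preset(manifest["preset"]),
        kind=manifest["kind"],
        traces=traces,
        group_labels=np.asarray(manifest["group_labels"], dtype=object),
        truth=pd.DataFrame.from_records(manifest["truth"]),
        seed=manifest.get("seed"),
    )


# --------------------------------------------------------------------------
# spot images
# --------------------------------------------------------------------------

def write_spot_field(prefix: str | Path, field: SpotField) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(f"{prefix}_green.tif", field.green.astype(np.float32))
    tifffile.imwrite(f"{prefix}_red.tif", field.red.astype(np.float32))
    field.truth.to_csv(f"{prefix}_truth.csv", index=False)


def read_spot_field(prefix: str | Path, psf_sigma: float = 1.5,
                    channel_offset: tuple[float, float] = (0.0, 0.0)) -> SpotField:
    prefix = Path(prefix)
    return SpotField(
        green=tifffile.imread(f"{prefix}_green.tif").astype(float),
        red=tifffile.imread(f"{prefix}_red.tif").astype(float),
        truth=pd.read_csv(f"{prefix}_truth.csv"),
        psf_sigma=psf_sigma,
        channel_offset=channel_offset,
    )


# --------------------------------------------------------------------------
# TCSPC
# --------------------------------------------------------------------------

def write_tcspc(path: str | Path, hist: TcspcHistogram) -> None:
    data = np.column_stack([hist.bin_edges[:-1], hist.counts])
    header = "bin_left_ns counts"
    np.savetxt(path, data, header=header, fmt=["%.6g", "%d"])


def read_tcspc(path: str | Path) -> TcspcHistogram:
    data = np.loadtxt(path, comments="#")
    lefts, counts = data[:, 0], data[:, 1]
    width = lefts[1] - lefts[0]
    edges = np.append(lefts, lefts[-1] + width)
    return TcspcHistogram(bin_edges=edges, counts=counts.astype(int))


# --------------------------------------------------------------------------
# SAXS
# --------------------------------------------------------------------------

def read_saxs(path: str | Path) -> SaxsCurve:
    """Whitespace-delimited (q, I[, sigma]) with '#' comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SaxsCurve(q=data[:, 0], intensity=data[:, 1], sigma=sigma)


def write_saxs(path: str | Path, curve: SaxsCurve) -> None:
    cols = [curve.q, curve.intensity]
    header = "q_invA intensity"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.8g")


def write_pofr(path: str | Path, pofr: Pofr) -> None:
    np.savetxt(path, np.column_stack([pofr.r, pofr.p]),
               header=f"r_A p_r  (dmax={pofr.dmax:g} alpha={pofr.alpha:g})",
               fmt="%.8g")


def write_fit(path: str | Path, q: np.ndarray, i_expt: np.ndarray,
              i_model: np.ndarray, residuals: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([q, i_expt, i_model, residuals]),
               header="q_invA I_expt I_model residual", fmt="%.8g")
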