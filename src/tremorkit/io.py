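"""Plain-text readers and writers for the package's file formats.

Time-series files carry one header line ``fs_hz=<float>`` followed by one
voltage sample per row. Spike-time files are two-column delimited text
(``time_s``, ``label`` in {S, C, U}); unlabelled files may omit the label
column. Spectra and band tables are delimited text with a header row.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SignalTrace, SpikeTrain
from .spectral import BandPower, PowerSpectrum
from .spiketrain import SpikeStats

__all__ = [
    "write_trace",
    "read_trace",
    "write_spike_train",
    "read_spike_train",
    "write_spectrum",
    "read_spectrum",
    "write_band_table",
    "write_stats_table",
    "write_stim_log",
]


def write_trace(trace: SignalTrace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"fs_hz={trace.fs_hz!r}\n")
        np.savetxt(fh, trace.samples, fmt="%.9g")


def read_trace(path: str | Path) -> SignalTrace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("fs_hz="):
            raise ValueError(f"{path}: expected 'fs_hz=<float>' header")
        fs_hz = float(header.split("=", 1)[1])
        samples = np.loadtxt(fh, ndmin=1)
    return SignalTrace(samples, fs_hz)


def write_spike_train(train: SpikeTrain, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["time_s", "label"])
        for t, lab in zip(train.times_s, train.labels):
            writer.writerow([f"{t:.9f}", lab])


def read_spike_train(path: str | Path, duration_s: float | None = None) -> SpikeTrain:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    labels = df["label"].to_numpy(dtype="U1") if "label" in df.columns else None
    return SpikeTrain(df["time_s"].to_numpy(), labels, duration_s=duration_s)


def write_spectrum(ps: PowerSpectrum, path: str | Path) -> None:
    df = pd.DataFrame({"freq_hz": ps.freqs_hz, "power_v2": ps.power_v2})
    df.to_csv(path, sep="\t", index=False)


def read_spectrum(
    path: str | Path, window: str = "hann", nfft: int | None = None
) -> PowerSpectrum:
    df = pd.read_csv(path, sep="\t")
    freqs = df["freq_hz"].to_numpy()
    res = float(freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    return PowerSpectrum(
        freqs, df["power_v2"].to_numpy(), resolution_hz=res, window=window,
        nfft=nfft if nfft is not None else 2 * (freqs.size - 1),
    )


def write_band_table(bands: list[BandPower], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"lo_hz": b.lo_hz, "hi_hz": b.hi_hz, "power_v2": b.power_v2} for b in bands]
    )
    df.to_csv(path, sep="\t", index=False)


def write_stats_table(stats: dict[str, SpikeStats], path: str | Path) -> None:
    """One row per cell, suitable for downstream group statistics."""
    rows = []
    for cell, s in stats.items():
        rows.append(
            {
                "cell": cell,
                "rate_hz": s.rate_hz,
                "cv": s.cv,
                "cv2": s.cv2,
                "pre_cs_pause_s": s.pre_cs_pause_s,
                "post_cs_pause_s": s.post_cs_pause_s,
                "ss_cs_ratio": s.ss_cs_ratio,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_stim_log(log, out_dir: str | Path) -> None:
    """StimLog as three delimited files: pulses, epochs, band-power series."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "pulses.txt", log.pulse_times_s, fmt="%.6f",
               header="time_s", comments="")
    with (out_dir / "epochs.txt").open("w") as fh:
        fh.write("start_s\tstop_s\n")
        for start, stop in log.stim_epochs:
            fh.write(f"{start:.6f}\t{stop:.6f}\n")
    np.savetxt(out_dir / "band_power.txt", log.band_power_series,
               fmt="%.6f\t%.9g", header="time_s\tpower_v2", comments="")
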