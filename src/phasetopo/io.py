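"""File I/O: records, montages, schedules, label grids and maps.

Text formats throughout: records are TSV with one column per channel
(header row of channel names, one row per sample); montages are TSV of
``name x y z``; schedules are TSV of ``onset_sample condition`` (0-based
onsets).  EDF records are read through MNE.  Every written artifact can be
accompanied by a JSON sidecar recording the configuration that produced
it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import mask_to_hex
from .maps import TFTMap
from .mcps import ClusterRecord
from .sim_eeg import ElectrodeMontage, FlashSchedule

__all__ = [
    "read_record",
    "write_record_tsv",
    "read_montage_tsv",
    "write_montage_tsv",
    "read_schedule_tsv",
    "write_schedule_tsv",
    "write_cluster_record_tsv",
    "write_tft_tsv",
    "write_tfl_tsv",
    "write_sidecar",
]


def read_record(
    path: str | Path,
    fmt: str | None = None,
    montage: ElectrodeMontage | None = None,
    fs: float | None = None,
) -> tuple[np.ndarray, float | None, list[str]]:
    """Read a multichannel record as (channels x samples, fs, names).

    ``fmt`` is ``"tsv"`` or ``"edf"`` (inferred from the suffix when
    omitted).  When a montage is given, channels are re-ordered to the
    canonical montage order and a missing channel is an explicit error.
    TSV files carry no rate, so ``fs`` passes through; EDF headers win.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
        names = [str(c) for c in frame.columns]
        data = frame.to_numpy(dtype=float).T
    elif fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = list(raw.ch_names)
        data = raw.get_data()
        fs = float(raw.info["sfreq"])
    else:
        raise ValueError(f"unknown record format {fmt!r}")
    if montage is not None:
        missing = [n for n in montage.names if n not in names]
        if missing:
            raise ValueError(f"record is missing montage channels: {missing}")
        order = [names.index(n) for n in montage.names]
        data = data[order]
        names = list(montage.names)
    return data, fs, names


def write_record_tsv(path: str | Path, data: np.ndarray, names: list[str]) -> None:
    """Write channels x samples data as a TSV with channel-name header."""
    pd.DataFrame(np.asarray(data).T, columns=list(names)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_montage_tsv(path: str | Path, montage: ElectrodeMontage) -> None:
    pd.DataFrame(
        {
            "name": montage.names,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_montage_tsv(path: str | Path) -> ElectrodeMontage:
    frame = pd.read_csv(path, sep="\t")
    return ElectrodeMontage(
        tuple(frame["name"].astype(str)), frame[["x", "y", "z"]].to_numpy(float)
    )


def write_schedule_tsv(path: str | Path, schedule: FlashSchedule) -> None:
    pd.DataFrame(schedule.events, columns=["onset_sample", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def read_schedule_tsv(
    path: str | Path, isi_ms: float = 125.0, epoch_window: tuple[int, int] = (0, 256)
) -> FlashSchedule:
    frame = pd.read_csv(path, sep="\t")
    events = tuple(
        (int(o), str(c)) for o, c in zip(frame["onset_sample"], frame["condition"])
    )
    return FlashSchedule(events, isi_ms, epoch_window)


def write_cluster_record_tsv(
    outdir: str | Path, record: ClusterRecord, names: list[str]
) -> list[Path]:
    """One channels x samples TSV of hex labels per band: ``ceeg_band<k>.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_ch = record.n_channels
    paths = []
    for k in range(record.n_bands):
        hexed = np.empty((n_ch, record.n_samples), dtype=object)
        for j in range(n_ch):
            hexed[j] = [mask_to_hex(int(m), n_ch) for m in record.labels[k, j]]
        frame = pd.DataFrame(hexed.T, columns=list(names))
        p = outdir / f"ceeg_band{k:02d}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def write_tft_tsv(path: str | Path, tft: TFTMap, names: list[str]) -> None:
    """Long-format TFT/iTFT table: band, window, channel, label."""
    n_ch = len(names)
    rows = [
        (k, w, names[j], mask_to_hex(int(tft.labels[k, w, j]), n_ch))
        for k in range(tft.labels.shape[0])
        for w in range(tft.n_windows)
        for j in range(n_ch)
    ]
    pd.DataFrame(rows, columns=["band", "window", "channel", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_tfl_tsv(path: str | Path, distances: np.ndarray) -> None:
    """Long-format TFL table: band, window, distance."""
    rows = [
        (k, w, int(distances[k, w]))
        for k in range(distances.shape[0])
        for w in range(distances.shape[1])
    ]
    pd.DataFrame(rows, columns=["band", "window", "distance"]).to_csv(
        path, sep="\t", index=False
    )


def write_sidecar(path: str | Path, payload: dict) -> None:
    """JSON sidecar with the configuration that produced an artifact."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
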