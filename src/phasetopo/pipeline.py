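"""End-to-end orchestration: phase extraction -> clustering -> labeling ->
segmentation -> TFT / iTFT / TFL artifacts.

The pipeline clusters the continuous record first and segments the labeled
record afterwards, so the hexadecimal label universe is shared between
conditions and identical words always denote identical channel sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as ptio
from .contrast import tfl_map
from .maps import build_itft, build_tft, segment_epochs, tf_power_map
from .mcps import cluster_series
from .sim_eeg import ElectrodeMontage, FlashSchedule
from .tf_phase import analytic_decompose, center_frequencies, instantaneous_phase, power

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable parameters of one analysis run.

    Defaults follow the standard analysis settings: 12 geometric bands
    between 1 and 12 Hz, 4-cycle Morlet wavelets, synchrony threshold
    ``r = 0.9``, strict mode majority ``rho = 50`` percent, window
    ``upsilon = 16`` samples.
    """

    fs: float = 256.0
    fmin: float = 1.0
    fmax: float = 12.0
    k_bands: int = 12
    cycles: float = 4.0
    r: float = 0.9
    rho: float = 50.0
    upsilon: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError("threshold r must satisfy 0 < r < 1")
        if not 0 <= self.rho < 100:
            raise ValueError("mode threshold rho must be in [0, 100)")
        if self.upsilon < 1:
            raise ValueError("window size upsilon must be >= 1")
        if not 0 < self.fmin < self.fmax <= self.fs / 2:
            raise ValueError("need 0 < fmin < fmax <= fs/2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """In-memory artifacts of one run (also written to disk when asked)."""

    phase: object
    power: object
    clusters: object
    tft: object  # whole-record TFT map
    itft: dict  # condition -> iTFT map
    tfl: dict  # channel name -> TFLMap (first vs second condition)
    label_universe: set[str]


def run_pipeline(
    data: np.ndarray,
    montage: ElectrodeMontage,
    config: PipelineConfig,
    schedule: FlashSchedule | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis on a channels x samples record.

    With a schedule, per-condition iTFT maps and per-channel TFL contrast
    maps (first condition versus second) are produced; without one, only
    the whole-record TFT map.  Deterministic given the inputs.
    """
    from .labeling import mask_to_hex

    if data.shape[0] != montage.n_channels:
        raise ValueError("record row count does not match the montage")
    grid = center_frequencies(config.fmin, config.fmax, config.k_bands)
    analytic = analytic_decompose(data, grid, config.cycles, config.fs)
    phase = instantaneous_phase(analytic)
    pw = power(analytic)
    del analytic
    clusters = cluster_series(phase, config.r)
    tft = build_tft(clusters, config.upsilon, config.rho)
    universe = {
        mask_to_hex(int(m), montage.n_channels) for m in np.unique(clusters.labels)
    }

    itft: dict = {}
    tfl: dict = {}
    if schedule is not None and schedule.events:
        stacks = segment_epochs(clusters, schedule)
        for condition, stack in stacks.items():
            itft[condition] = build_itft(
                stack, config.upsilon, config.rho, fs=config.fs, grid=grid
            )
        conditions = list(itft)
        if len(conditions) >= 2:
            a, b = itft[conditions[0]], itft[conditions[1]]
            for j, name in enumerate(montage.names):
                tfl[name] = tfl_map(a, b, j, montage.n_channels)

    result = PipelineResult(
        phase=phase, power=pw, clusters=clusters, tft=tft, itft=itft,
        tfl=tfl, label_universe=universe,
    )
    if outdir is not None:
        _write_artifacts(result, montage, config, schedule, Path(outdir))
    return result


def _write_artifacts(
    result: PipelineResult,
    montage: ElectrodeMontage,
    config: PipelineConfig,
    schedule: FlashSchedule | None,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(montage.names)
    ptio.write_cluster_record_tsv(outdir / "ceeg", result.clusters, names)
    ptio.write_tft_tsv(outdir / "tft.tsv", result.tft, names)
    for condition, m in result.itft.items():
        ptio.write_tft_tsv(outdir / f"itft_{condition}.tsv", m, names)
    for name, m in result.tfl.items():
        ptio.write_tfl_tsv(outdir / f"tfl_{name}.tsv", m.distances)
    for j, name in enumerate(names):
        grid_pw = tf_power_map(result.power, j, config.upsilon)
        np.savetxt(
            outdir / f"power_{name}.tsv", grid_pw, delimiter="\t", fmt="%.6g"
        )
    sidecar = {
        "config": config.to_dict(),
        "montage": names,
        "band_centers": list(result.clusters.grid.centers),
        "conditions": list(result.itft),
        "n_events": len(schedule.events) if schedule else 0,
    }
    ptio.write_sidecar(outdir / "run_config.json", sidecar)
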