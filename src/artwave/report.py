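"""Run summaries: per-probe extrema tables, waveform similarity, pipeline.

The comparison surface of a compliance-mismatch run is (i) per-probe
waveforms of wall shear stress, pressure, hoop stress and hoop strain over
the final cycle, (ii) a table of their cycle maxima/minima with flags for
which probe attains each absolute extremum, and (iii) pairwise waveform
similarities.  ``run_pipeline`` drives the whole chain from a YAML config
to a directory of tidy CSVs plus a JSON run report.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulsewave import SimulationResult
from .wallmech import hoop_series

__all__ = [
    "SegmentComparison",
    "summarize",
    "waveform_similarity",
    "similarity_matrix",
    "run_pipeline",
]

QUANTITIES = ("wss_Pa", "pressure_Pa", "hoop_stress_Pa", "hoop_strain")

#: soft threshold for the "pressures look alike across probes" check
SIMILARITY_THRESHOLD = 0.95


@dataclass
class SegmentComparison:
    """Per-probe cycle extrema and which probe attains each absolute extremum.

    ``table`` is indexed by probe position (mm) with max/min columns per
    quantity; ``orderings`` maps each quantity to the probe (mm) with the
    largest absolute extremum, or ``"tie"`` when probes are
    indistinguishable.
    """

    table: pd.DataFrame
    orderings: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "table": json.loads(self.table.to_json(orient="index")),
                "orderings": self.orderings,
            },
            indent=2,
        )


def _probe_frames(result: SimulationResult) -> dict:
    """Final-cycle frames per probe with hoop stress/strain attached."""
    frames = {}
    for xp, df in result.probes.items():
        material = result.vessel.material_at(xp)
        stress, strain = hoop_series(
            df["pressure_Pa"].to_numpy(),
            df["area_m2"].to_numpy(),
            result.vessel.geometry,
            material,
        )
        out = df.copy()
        out["hoop_stress_Pa"] = stress
        out["hoop_strain"] = strain
        frames[xp] = out
    return frames


def summarize(result: SimulationResult) -> SegmentComparison:
    """Cycle extrema of WSS, pressure, hoop stress and strain per probe.

    Extrema are taken over the final (converged) cycle only.  The ordering
    flag for each quantity names the probe with the largest absolute
    extremum; exact ties (e.g. an all-zero run) are reported as ``"tie"``.
    """
    frames = _probe_frames(result)
    if not frames:
        raise ValueError("result has no probe series")
    rows = {}
    for xp, df in frames.items():
        row = {}
        for q in QUANTITIES:
            row[f"max_{q}"] = float(df[q].max())
            row[f"min_{q}"] = float(df[q].min())
        rows[round(xp * 1000, 6)] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "probe_mm"

    orderings = {}
    for q in QUANTITIES:
        absmax = np.maximum(
            table[f"max_{q}"].abs(), table[f"min_{q}"].abs()
        )
        top = absmax.max()
        winners = absmax.index[np.isclose(absmax, top, rtol=1e-12, atol=0.0)]
        orderings[q] = "tie" if len(winners) != 1 else float(winners[0])
    return SegmentComparison(table=table, orderings=orderings)


def waveform_similarity(series_a, series_b) -> float:
    """Normalised zero-lag cross-correlation after mean removal, in [0, 1].

    1 for identical shapes up to positive scaling; anti-correlated shapes
    clamp to 0.  Two constant series count as identical (1); a constant
    against a varying series scores 0.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 and nb == 0.0:
        return 1.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    r = float(np.dot(a, b) / (na * nb))
    return max(r, 0.0)


def similarity_matrix(result: SimulationResult, column: str = "pressure_Pa"):
    """Pairwise waveform similarity of a probe quantity across probes."""
    keys = sorted(result.probes)
    n = len(keys)
    mat = pd.DataFrame(
        np.ones((n, n)),
        index=[round(k * 1000, 6) for k in keys],
        columns=[round(k * 1000, 6) for k in keys],
    )
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            if i < j:
                s = waveform_similarity(
                    result.probes[ki][column], result.probes[kj][column]
                )
                mat.iloc[i, j] = mat.iloc[j, i] = s
    return mat


def run_pipeline(config_path, outdir, verbose: bool = False) -> dict:
    """Full chain: config -> waveform -> 1D simulation -> wall mechanics
    -> summaries, written as CSVs plus ``report.json`` under ``outdir``.

    Returns the report dict.  Stage failures propagate with a stage-labelled
    message.
    """
    from .model import load_config
    from .pulsewave import PulseWaveModel
    from .waveform import default_waveform_params, generate_waveform
    from .womersley import reynolds_number, womersley_number

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    cfg = _stage("config", lambda: load_config(config_path))
    model = _stage("config", lambda: PulseWaveModel.from_config(config_path))
    if model.waveform is None:
        model.waveform = _stage(
            "waveform",
            lambda: generate_waveform(
                default_waveform_params(
                    model.fluid,
                    model.vessel.geometry.inner_diameter,
                    period=cfg["period"],
                )
            ),
        )
    waveform = model.waveform
    waveform.to_csv(outdir / "inlet_waveform.csv")

    alpha = womersley_number(model.fluid, model.vessel.geometry, cfg["period"])
    re_range = (
        reynolds_number(
            model.fluid,
            model.vessel.geometry.inner_diameter,
            float(np.min(np.abs(waveform.values))),
        ),
        reynolds_number(
            model.fluid,
            model.vessel.geometry.inner_diameter,
            float(np.max(np.abs(waveform.values))),
        ),
    )

    result = _stage("simulate", model.run)
    frames = _stage("wall_mechanics", lambda: _probe_frames(result))
    for xp, df in frames.items():
        df.to_csv(outdir / f"probe_{int(round(xp * 1000))}mm.csv", index=False)

    comparison = _stage("summarize", lambda: summarize(result))
    comparison.table.to_csv(outdir / "segment_comparison.csv")
    sim_p = similarity_matrix(result, "pressure_Pa")
    sim_w = similarity_matrix(result, "wss_Pa")
    min_sim = float(np.min(sim_p.to_numpy()))

    report = {
        "config": str(config_path),
        "womersley_number": alpha,
        "reynolds_range": list(re_range),
        "diagnostics": _jsonable(result.diagnostics),
        "orderings": comparison.orderings,
        "pressure_similarity": json.loads(sim_p.to_json()),
        "wss_similarity": json.loads(sim_w.to_json()),
        "pressure_similarity_min": min_sim,
        "pressure_similarity_ok": bool(min_sim >= SIMILARITY_THRESHOLD),
        "n_probes": len(frames),
    }
    if verbose and not report["pressure_similarity_ok"]:
        print(
            f"warning: min pressure similarity {min_sim:.3f} "
            f"< {SIMILARITY_THRESHOLD}"
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def plot_probe_waveforms(result: SimulationResult, column: str = "wss_Pa",
                         ax=None):
    """Overlay one probe quantity across probes (matplotlib required)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frames = _probe_frames(result)
    for xp, df in sorted(frames.items()):
        ax.plot(df["time_s"], df[column], label=f"L = {xp * 1000:.0f} mm")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(column)
    ax.legend()
    return ax
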