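"""Plain-text and TIFF I/O for movies, traces, matrices, tracks and intervals.

Formats:

- FRAP movies: multi-page TIFF plus a JSON sidecar carrying the schedule, ROI
  geometry, anchors and (optionally) the generative ground truth.
- Traces: CSV with columns frame, time_s, I_bleach, I_nonbleach, I_background
  and a ``# bleach_after=N`` comment header.
- Contact matrices: dense TSV with a metadata comment header, or a two-table
  bins/pixels layout following the cool convention (upper triangle only).
- Insulation tracks as bedGraph; intervals as BED; pileups as TSV matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .hic import ContactMatrix, InsulationTrack
from .preprocess import FrapTrace
from .synthetic import AcquisitionSchedule, FrapMovie, MovieGroundTruth, TwoStateKinetics


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_frap_movie(path, movie: FrapMovie) -> None:
    """Write a movie as multi-page TIFF + JSON sidecar (same stem, .json)."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "schedule": {
            "frame_times": movie.schedule.frame_times.tolist(),
            "bleach_after": movie.schedule.bleach_after,
            "phase_boundary": movie.schedule.phase_boundary,
        },
        "roi_diameter_um": movie.roi_diameter_um,
        "pixel_size_um": movie.pixel_size_um,
        "roi_anchors": {str(k): list(v) for k, v in movie.roi_anchors.items()},
        "truth": None,
    }
    if movie.truth is not None:
        t = movie.truth
        meta["truth"] = {
            "kinetics": vars(t.kinetics),
            "photobleach_rate": t.photobleach_rate,
            "background_level": t.background_level,
            "prebleach_intensity": t.prebleach_intensity,
            "bleach_depth": t.bleach_depth,
            "drift_velocity": list(t.drift_velocity),
            "noise_sd": t.noise_sd,
            "seed": t.seed,
        }
    _sidecar(path).write_text(json.dumps(meta))


def read_frap_movie(path) -> FrapMovie:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    sched = AcquisitionSchedule(
        frame_times=np.array(meta["schedule"]["frame_times"]),
        bleach_after=meta["schedule"]["bleach_after"],
        phase_boundary=meta["schedule"]["phase_boundary"],
    )
    truth = None
    if meta["truth"] is not None:
        t = meta["truth"]
        truth = MovieGroundTruth(
            kinetics=TwoStateKinetics(**t["kinetics"]),
            photobleach_rate=t["photobleach_rate"],
            background_level=t["background_level"],
            prebleach_intensity=t["prebleach_intensity"],
            bleach_depth=t["bleach_depth"],
            drift_velocity=tuple(t["drift_velocity"]),
            noise_sd=t["noise_sd"],
            seed=t["seed"],
        )
    return FrapMovie(
        frames=frames,
        schedule=sched,
        roi_diameter_um=meta["roi_diameter_um"],
        pixel_size_um=meta["pixel_size_um"],
        roi_anchors={int(k): tuple(v) for k, v in meta["roi_anchors"].items()},
        truth=truth,
    )


def write_trace(path, trace: FrapTrace) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(trace.n_frames),
            "time_s": trace.time_s,
            "I_bleach": trace.i_bleach,
            "I_nonbleach": trace.i_nonbleach,
            "I_background": trace.i_background,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# bleach_after={trace.bleach_after}\n")
        df.to_csv(fh, index=False)


def read_trace(path) -> FrapTrace:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# bleach_after="):
            raise ValueError("trace file missing '# bleach_after=' header")
        bleach_after = int(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    return FrapTrace(
        time_s=df["time_s"].to_numpy(),
        i_bleach=df["I_bleach"].to_numpy(),
        i_nonbleach=df["I_nonbleach"].to_numpy(),
        i_background=df["I_background"].to_numpy(),
        bleach_after=bleach_after,
    )


def write_matrix_tsv(path, matrix: ContactMatrix) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# resolution_bp={matrix.resolution_bp} chrom={matrix.chrom} start={matrix.start}\n"
        )
        np.savetxt(fh, matrix.counts, delimiter="\t", fmt="%.10g")


def read_matrix_tsv(path) -> ContactMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("matrix TSV missing metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ContactMatrix(
        counts,
        resolution_bp=int(meta["resolution_bp"]),
        chrom=meta.get("chrom", "chrS"),
        start=int(meta.get("start", 0)),
    )


def write_cool_tables(prefix, matrix: ContactMatrix) -> tuple[Path, Path]:
    """Write bins/pixels tables (cool convention) as ``<prefix>.bins.tsv`` and
    ``<prefix>.pixels.tsv``; pixels hold the non-zero upper triangle."""
    prefix = Path(prefix)
    n = matrix.n_bins
    starts = matrix.start + np.arange(n) * matrix.resolution_bp
    bins = pd.DataFrame(
        {"chrom": matrix.chrom, "start": starts, "end": starts + matrix.resolution_bp}
    )
    iu = np.triu_indices(n)
    vals = matrix.counts[iu]
    nz = vals != 0
    pixels = pd.DataFrame(
        {"bin1_id": iu[0][nz], "bin2_id": iu[1][nz], "count": vals[nz]}
    )
    bins_path = prefix.with_suffix(".bins.tsv")
    pixels_path = prefix.with_suffix(".pixels.tsv")
    bins.to_csv(bins_path, sep="\t", index=False)
    pixels.to_csv(pixels_path, sep="\t", index=False)
    return bins_path, pixels_path


def read_cool_tables(bins_path, pixels_path) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t")
    pixels = pd.read_csv(pixels_path, sep="\t")
    if bins["chrom"].nunique() != 1:
        raise ValueError("only single-chromosome matrices are supported")
    n = len(bins)
    res = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    counts = np.zeros((n, n))
    i = pixels["bin1_id"].to_numpy(dtype=int)
    j = pixels["bin2_id"].to_numpy(dtype=int)
    v = pixels["count"].to_numpy(dtype=float)
    counts[i, j] = v
    counts[j, i] = v
    return ContactMatrix(
        counts,
        resolution_bp=res,
        chrom=str(bins["chrom"].iloc[0]),
        start=int(bins["start"].iloc[0]),
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_insulation_bedgraph(path, track: InsulationTrack) -> None:
    starts = track.start + np.arange(track.n_bins) * track.resolution_bp
    rows = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts,
            "end": starts + track.resolution_bp,
            "score": track.score,
        }
    )[track.valid]
    rows.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_pileup_tsv(path, pileup: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(pileup), delimiter="\t", fmt="%.10g")
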