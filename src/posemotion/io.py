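"""Reading per-frame keypoint JSON and the package's tabular CSV dialect.

A pose-estimation run emits one JSON document per video frame, each with a
``people`` array whose entries carry flat ``[x0, y0, c0, x1, y1, c1, ...]``
keypoint arrays. :func:`aggregate_frames` collects a clip's frame files into
a single :class:`~posemotion.models.PoseSequence`, and
:func:`write_table` / :func:`read_table` persist that sequence losslessly as
a CSV with interleaved per-point columns ``x0,y0,c0,x1,y1,c1,...`` plus a
metadata comment line carrying model, fps, and clip id.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import FramePose, KeypointModelSpec, PoseSequence, get_model

__all__ = [
    "parse_frame_file",
    "serialize_frame",
    "collect_frame_files",
    "aggregate_frames",
    "convert_clip",
    "write_table",
    "read_table",
    "write_field",
    "read_field",
    "write_series",
    "read_series",
    "DialectError",
]

PERSON_POLICIES = ("first", "highest_mean_confidence", "error_if_multiple")

# Frame files are ordered by the last run of digits before the extension,
# e.g. "clip_000000000042_keypoints.json" -> 42.
_FRAME_NUMBER_RE = re.compile(r"(\d+)(?=\D*$)")


class DialectError(ValueError):
    """A CSV file does not conform to the package's tabular dialect."""


def parse_frame_file(
    json_text: str,
    model: str | KeypointModelSpec,
    person_policy: str = "first",
    frame_index: int = 0,
    filename: str = "<string>",
) -> FramePose:
    """Extract one person's keypoints from a per-frame JSON document.

    When several people were detected, ``person_policy`` selects one:
    ``"first"`` (array order), ``"highest_mean_confidence"``, or
    ``"error_if_multiple"``. An empty ``people`` array yields an all-zero
    frame — the convention for a failed fit, which cleaning later imputes.
    """
    model = get_model(model)
    if person_policy not in PERSON_POLICIES:
        raise ValueError(
            f"person_policy must be one of {PERSON_POLICIES}, got {person_policy!r}"
        )
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {filename}: {exc}") from exc
    people = doc.get("people")
    if people is None:
        raise ValueError(f"{filename}: document has no 'people' array")

    if not people:
        zeros = np.zeros(model.n_points)
        return FramePose(frame_index, zeros.copy(), zeros.copy(), zeros.copy())

    triplets = []
    for person in people:
        flat = np.asarray(person.get(model.json_key, []), dtype=float)
        if flat.size != 3 * model.n_points:
            raise ValueError(
                f"{filename}: keypoint array of length {flat.size} does not "
                f"match model {model.name!r} (expected {3 * model.n_points})"
            )
        triplets.append(flat.reshape(model.n_points, 3))

    if len(triplets) > 1:
        if person_policy == "error_if_multiple":
            raise ValueError(
                f"{filename}: {len(triplets)} people detected but "
                "person_policy='error_if_multiple'"
            )
        if person_policy == "highest_mean_confidence":
            means = [t[:, 2].mean() for t in triplets]
            chosen = triplets[int(np.argmax(means))]
        else:
            chosen = triplets[0]
    else:
        chosen = triplets[0]

    return FramePose(frame_index, chosen[:, 0], chosen[:, 1], chosen[:, 2])


def serialize_frame(pose: FramePose, model: str | KeypointModelSpec) -> str:
    """Render a frame back to the per-frame JSON schema (round-trip inverse
    of :func:`parse_frame_file`)."""
    model = get_model(model)
    if pose.n_points != model.n_points:
        raise ValueError(
            f"frame has {pose.n_points} points, model {model.name!r} "
            f"has {model.n_points}"
        )
    if pose.is_zero():
        people = []
    else:
        flat = np.column_stack([pose.x, pose.y, pose.c]).ravel().tolist()
        people = [{"person_id": [-1], model.json_key: flat}]
    return json.dumps({"version": 1.3, "people": people})


def frame_number(path: str | Path) -> int:
    """Frame index encoded in a filename's trailing digit run."""
    m = _FRAME_NUMBER_RE.search(Path(path).stem)
    if m is None:
        raise ValueError(f"no frame number found in filename {Path(path).name!r}")
    return int(m.group(1))


def collect_frame_files(
    input_dir: str | Path, pattern: str = "*.json"
) -> list[Path]:
    """List a directory's frame files sorted by their numeric frame suffix."""
    files = sorted(Path(input_dir).glob(pattern), key=frame_number)
    return files


def aggregate_frames(
    frame_files: Sequence[str | Path] | Iterable[str | Path],
    model: str | KeypointModelSpec,
    fps: float = 25.0,
    person_policy: str = "first",
    source_id: str | None = None,
    on_gap: str = "error",
) -> PoseSequence:
    """Combine an ordered list of per-frame JSON files into one sequence.

    Files must cover a gapless, 0-based frame range (taken from each
    filename's numeric suffix). ``on_gap="zero"`` fills missing frames with
    all-zero poses instead of raising.
    """
    model = get_model(model)
    files = [Path(f) for f in frame_files]
    if on_gap not in ("error", "zero"):
        raise ValueError("on_gap must be 'error' or 'zero'")
    indexed = sorted((frame_number(f), f) for f in files)
    seen = [i for i, _ in indexed]
    if len(set(seen)) != len(seen):
        dupes = sorted({i for i in seen if seen.count(i) > 1})
        raise ValueError(f"duplicate frame indices in input files: {dupes}")

    n_total = (seen[-1] + 1) if seen else 0
    missing = sorted(set(range(n_total)) - set(seen))
    if missing and on_gap == "error":
        raise ValueError(
            f"missing frame files for indices {missing}; pass on_gap='zero' "
            "to insert all-zero frames"
        )

    by_index = dict(indexed)
    frames: list[FramePose] = []
    for t in range(n_total):
        if t in by_index:
            path = by_index[t]
            frames.append(
                parse_frame_file(
                    path.read_text(),
                    model,
                    person_policy=person_policy,
                    frame_index=t,
                    filename=str(path),
                )
            )
        else:
            zeros = np.zeros(model.n_points)
            frames.append(FramePose(t, zeros.copy(), zeros.copy(), zeros.copy()))

    if source_id is None:
        source_id = _common_stem(files)
    return PoseSequence.from_frames(frames, model, fps=fps, source_id=source_id)


def _common_stem(files: Sequence[Path]) -> str:
    """Clip identifier shared by a set of frame filenames (digits and the
    conventional "_keypoints" suffix stripped)."""
    if not files:
        return "clip"
    stem = files[0].stem
    stem = _FRAME_NUMBER_RE.sub("", stem)
    stem = stem.replace("_keypoints", "").rstrip("_-.")
    return stem or "clip"


def convert_clip(
    input_dir: str | Path,
    model: str | KeypointModelSpec,
    output_dir: str | Path | None = None,
    fps: float = 25.0,
    pattern: str = "*.json",
    person_policy: str = "first",
    source_id: str | None = None,
    on_gap: str = "error",
) -> Path:
    """Aggregate a clip's frame JSON directory and write the CSV table.

    The output filename is the clip stem with the model name appended
    (e.g. ``clip_body25.csv``). Returns the written path.
    """
    model = get_model(model)
    files = collect_frame_files(input_dir, pattern)
    if not files:
        raise FileNotFoundError(
            f"no frame files matching {pattern!r} in {input_dir}"
        )
    seq = aggregate_frames(
        files, model, fps=fps, person_policy=person_policy,
        source_id=source_id, on_gap=on_gap,
    )
    out_dir = Path(output_dir) if output_dir is not None else Path(input_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / f"{seq.source_id}_{model.name}.csv"
    write_table(seq, out_path)
    return out_path


# ---------------------------------------------------------------------------
# CSV dialect

def _header(model: KeypointModelSpec) -> list[str]:
    cols = []
    for i in range(model.n_points):
        cols += [f"x{i}", f"y{i}", f"c{i}"]
    return cols


def write_table(seq: PoseSequence, path: str | Path) -> Path:
    """Write a sequence as CSV: metadata comment line, header, one row per
    frame, full float precision (lossless round trip)."""
    path = Path(path)
    cols = _header(seq.model)
    data = np.empty((seq.n_frames, 3 * seq.n_points))
    data[:, 0::3] = seq.x
    data[:, 1::3] = seq.y
    data[:, 2::3] = seq.c
    frame = pd.DataFrame(data, columns=cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(
            f"# posemotion model={seq.model.name} fps={seq.fps!r} "
            f"source_id={seq.source_id}\n"
        )
        frame.to_csv(fh, index=False, float_format="%.17g")
    return path


_META_RE = re.compile(
    r"#\s*posemotion\s+model=(\S+)\s+fps=(\S+)\s+source_id=(.*)"
)


def read_table(
    path: str | Path, model: str | KeypointModelSpec | None = None
) -> PoseSequence:
    """Read a CSV table written by :func:`write_table` back into a sequence.

    ``model`` may be omitted when the file carries the metadata line; if
    given, it must agree with the file's column count.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        meta = _META_RE.match(first.strip())
        if meta:
            file_model, fps, source_id = (
                meta.group(1), float(meta.group(2)), meta.group(3).strip()
            )
            body_start = fh.tell()
        else:
            file_model, fps, source_id = None, 25.0, path.stem
            body_start = 0
        fh.seek(body_start)
        try:
            frame = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise DialectError(f"{path}: no header row") from None

    if model is None:
        if file_model is None:
            raise DialectError(
                f"{path}: no metadata line and no model given"
            )
        model = file_model
    model = get_model(model)
    if file_model is not None and get_model(file_model) != model:
        raise DialectError(
            f"{path}: file declares model {file_model!r}, caller asked for "
            f"{model.name!r}"
        )

    expected = _header(model)
    if list(frame.columns) != expected:
        raise DialectError(
            f"{path}: {len(frame.columns)} columns do not match model "
            f"{model.name!r} ({3 * model.n_points} expected)"
        )
    bad = frame.columns[frame.dtypes == object]
    if len(bad):
        for col in bad:
            rows = frame.index[
                pd.to_numeric(frame[col], errors="coerce").isna()
            ].tolist()
            if rows:
                raise DialectError(
                    f"{path}: non-numeric value at row {rows[0]}, column {col!r}"
                )
        frame = frame.apply(pd.to_numeric)

    data = frame.to_numpy(dtype=float)
    if data.size == 0:
        data = data.reshape(0, 3 * model.n_points)
    return PoseSequence(
        model,
        data[:, 0::3],
        data[:, 1::3],
        data[:, 2::3],
        fps=fps,
        source_id=source_id,
    )


# ---------------------------------------------------------------------------
# derivative tables (velocity/acceleration fields and motion series)

def _write_matrix(
    data: np.ndarray, columns: list[str], path: Path, meta: str
) -> None:
    frame = pd.DataFrame(np.atleast_2d(data), columns=columns)
    if data.size == 0:
        frame = pd.DataFrame(np.empty((0, len(columns))), columns=columns)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(meta + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def _read_matrix(path: Path, meta_re: re.Pattern) -> tuple[re.Match, np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        m = meta_re.match(first.strip())
        if not m:
            raise DialectError(f"{path}: missing or malformed metadata line")
        frame = pd.read_csv(fh, float_precision="round_trip")
    data = frame.to_numpy(dtype=float)
    if data.size == 0:
        data = data.reshape(0, len(frame.columns))
    return m, data


_FIELD_META_RE = re.compile(
    r"#\s*posemotion-field\s+quantity=(\S+)\s+axis=(\S+)\s+fps=(\S+)\s+"
    r"start_frame=(\d+)"
)
_SERIES_META_RE = re.compile(
    r"#\s*posemotion-series\s+quantity=(\S+)\s+fps=(\S+)\s+start_frame=(\d+)"
)


def write_field(field, stem: str | Path) -> tuple[Path, Path]:
    """Write a velocity or acceleration field as two axis CSVs.

    Files are ``<stem>_<quantity>_x.csv`` and ``..._y.csv`` — one row per
    frame transition, one column per point.
    """
    from .kinematics import AccelField, VelocityField  # local: avoid cycle

    if isinstance(field, VelocityField):
        u, w = field.vx, field.vy
    elif isinstance(field, AccelField):
        u, w = field.ax, field.ay
    else:
        raise TypeError(f"expected a kinematics field, got {type(field)}")
    stem = Path(stem)
    cols = [f"p{i}" for i in range(u.shape[1])]
    paths = []
    for axis, data in (("x", u), ("y", w)):
        meta = (
            f"# posemotion-field quantity={field.quantity} axis={axis} "
            f"fps={field.fps!r} start_frame={field.start_frame}"
        )
        path = stem.parent / f"{stem.name}_{field.quantity}_{axis}.csv"
        _write_matrix(data, cols, path, meta)
        paths.append(path)
    return paths[0], paths[1]


def read_field(path_x: str | Path, path_y: str | Path):
    """Read the two axis CSVs of a field back; inverse of :func:`write_field`."""
    from .kinematics import AccelField, VelocityField

    (m_x, u), (m_y, w) = (
        _read_matrix(Path(p), _FIELD_META_RE) for p in (path_x, path_y)
    )
    if m_x.group(1) != m_y.group(1) or m_x.group(3) != m_y.group(3):
        raise DialectError("axis files disagree on quantity or fps")
    if (m_x.group(2), m_y.group(2)) != ("x", "y"):
        raise DialectError(
            f"expected axis files in (x, y) order, got "
            f"({m_x.group(2)}, {m_y.group(2)})"
        )
    quantity, fps = m_x.group(1), float(m_x.group(3))
    if quantity == "velocity":
        return VelocityField(vx=u, vy=w, fps=fps)
    if quantity == "acceleration":
        return AccelField(ax=u, ay=w, fps=fps)
    raise DialectError(f"unknown field quantity {quantity!r}")


def write_series(series, path: str | Path) -> Path:
    """Write a motion series as a single-column CSV."""
    path = Path(path)
    meta = (
        f"# posemotion-series quantity={series.quantity} fps={series.fps!r} "
        f"start_frame={series.start_frame}"
    )
    _write_matrix(series.values.reshape(-1, 1), ["en"], path, meta)
    return path


def read_series(path: str | Path):
    """Read a motion series CSV; inverse of :func:`write_series`."""
    from .kinematics import MotionSeries

    m, data = _read_matrix(Path(path), _SERIES_META_RE)
    return MotionSeries(
        data.reshape(-1),
        quantity=m.group(1),
        fps=float(m.group(2)),
        start_frame=int(m.group(3)),
    )
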