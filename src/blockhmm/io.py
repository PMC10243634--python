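"""File formats: observation sequences, model JSON, block tables.

Observations are newline-delimited decimals (blank lines ignored) or,
in binary mode, contiguous little-endian IEEE-754 doubles.  Models are
JSON objects with keys ``n_states``, ``transitions`` (row-major),
``means``, ``variances``, ``initial``; reading validates the model
invariants and names the offending field.  Blocks export as a BED-like
tab-separated table (start, end, s1, s2).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hmm import HMMModel
from .wavelet import BlockSequence

__all__ = [
    "read_observations",
    "write_observations",
    "read_model",
    "write_model",
    "write_blocks",
]


def read_observations(path, binary: bool = False) -> np.ndarray:
    """Load an observation sequence from text or raw-double binary."""
    path = Path(path)
    if binary:
        raw = path.read_bytes()
        if len(raw) % 8:
            raise ValueError(
                f"{path}: truncated binary input, {len(raw)} bytes is not a "
                f"multiple of 8 (offset {len(raw) - len(raw) % 8})"
            )
        y = np.frombuffer(raw, dtype="<f8").astype(float)
    else:
        values = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    values.append(float(line))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: unparseable value {line!r}") from None
        y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError(f"{path}: empty observation sequence")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{path}: non-finite observation values")
    return y


def write_observations(y, path, binary: bool = False) -> None:
    path = Path(path)
    y = np.asarray(y, dtype=float).ravel()
    if binary:
        path.write_bytes(y.astype("<f8").tobytes())
    else:
        path.write_text("".join(f"{float(v)!r}\n" for v in y))


def read_model(path) -> HMMModel:
    """Parse and validate a model JSON file."""
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    for key in ("n_states", "transitions", "means", "variances", "initial"):
        if key not in doc:
            raise ValueError(f"{path}: missing field {key!r}")
    n = int(doc["n_states"])
    trans = np.asarray(doc["transitions"], dtype=float).reshape(n, n)
    try:
        return HMMModel(
            trans=trans,
            means=np.asarray(doc["means"], dtype=float),
            variances=np.asarray(doc["variances"], dtype=float),
            init=np.asarray(doc["initial"], dtype=float),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: invalid model: {exc}") from None


def write_model(model: HMMModel, path) -> None:
    """Serialize a model to JSON at full precision."""
    doc = {
        "n_states": model.n_states,
        "transitions": model.trans.tolist(),
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "initial": model.init.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def write_blocks(blocks: BlockSequence, path) -> None:
    """BED-like block table: start, end, s1, s2 (tab-separated)."""
    with Path(path).open("w") as fh:
        fh.write("start\tend\ts1\ts2\n")
        for b in blocks:
            fh.write(f"{b.start}\t{b.end}\t{b.s1!r}\t{b.s2!r}\n")
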