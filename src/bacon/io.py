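"""File formats, manifests and packaged synthetic fixtures.

Matrices travel as TSV (tab-separated, UTF-8, "." decimal) with an
optional label header row and column; manifests as JSON; MCMC sample
archives as a small binary layout (magic, version byte, header, then
bit-packed upper triangles) with a SHA-256 checksum recorded in the
side-car manifest.
"""

from __future__ import annotations

import hashlib
import json
import struct
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    Hyperparameters,
    StreamlineCounts,
    forward_simulate,
    n_pairs,
    validate_adjacency,
)
from .metrics import random_density_matched_graph

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_matrix",
    "write_matrix",
    "RunManifest",
    "write_sample_archive",
    "read_sample_archive",
    "FIXTURE_PRESETS",
    "generate_fixture",
]

_ARCHIVE_MAGIC = b"BCSA"
_ARCHIVE_VERSION = 1


# ---------------------------------------------------------------------------
# Matrix TSV/CSV
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"

def _read_frame(path: Path) -> tuple[np.ndarray, Optional[list[str]]]:
    sep = _sep_for(path)
    first = path.read_text(encoding="utf-8").splitlines()[0]
    fields = first.split(sep)
    def _numeric(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False
    has_labels = not all(_numeric(f) for f in fields if f != "")
    if has_labels:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        labels = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != labels:
            raise ValueError(f"{path}: row labels do not match column labels")
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        labels = None
    return df.to_numpy(), labels


def read_count_matrix(path) -> StreamlineCounts:
    """Read a K x K streamline count matrix from TSV/CSV.

    A non-numeric first row is treated as a label header (with matching
    row labels in the first column).  The matrix must be square, with
    non-negative integer entries and a zero diagonal; violations raise
    errors that name the offending cell.
    """
    path = Path(path)
    values, labels = _read_frame(path)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: expected a square matrix, got shape {values.shape}"
        )
    if not np.all(values == np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise ValueError(f"{path}: non-integer count at row {i}, column {j}")
    try:
        return StreamlineCounts(values.astype(np.int64), labels)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_count_matrix(counts: StreamlineCounts, path) -> None:
    path = Path(path)
    write_matrix(counts.counts, path, labels=counts.labels, fmt="%d")


def write_matrix(mat: np.ndarray, path, labels=None, fmt: str = "%.10g") -> None:
    """Write a square matrix as TSV/CSV, optionally with region labels."""
    path = Path(path)
    sep = _sep_for(path)
    mat = np.asarray(mat)
    with path.open("w", encoding="utf-8") as fh:
        if labels is not None:
            fh.write(sep + sep.join(labels) + "\n")
        for i, row in enumerate(mat):
            cells = [fmt % v for v in row]
            if labels is not None:
                cells.insert(0, labels[i])
            fh.write(sep.join(cells) + "\n")


def read_matrix(path) -> tuple[np.ndarray, Optional[list[str]]]:
    """Read a square numeric matrix (adjacency or probabilities) from TSV/CSV."""
    path = Path(path)
    values, labels = _read_frame(path)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {values.shape}")
    return values, labels


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record for an inference run."""

    hyperparameters: dict
    seed: Optional[int]
    n_regions: int
    n_chains: int
    n_samples: int
    acceptance_rates: dict
    diagnostics: dict = field(default_factory=dict)
    software: str = ""
    created: str = ""
    checksum_sha256: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Sample archive
# ---------------------------------------------------------------------------

def write_sample_archive(samples, directory) -> Path:
    """Write a GraphSampleSet to ``directory`` (samples.bin + manifest.json).

    Layout of samples.bin: magic ``BCSA``, one version byte, then
    little-endian uint16 K, uint32 n_samples, uint16 bytes-per-sample,
    followed by the int32 chain ids, int32 sweep indices, and the
    bit-packed upper-triangle rows.
    """
    from . import __version__  # deferred to avoid import cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, nbytes = samples.packed.shape
    header = _ARCHIVE_MAGIC + bytes([_ARCHIVE_VERSION]) + struct.pack(
        "<HIH", samples.n_regions, n, nbytes
    )
    payload = (
        header
        + np.asarray(samples.chain_ids, dtype="<i4").tobytes()
        + np.asarray(samples.sweep_indices, dtype="<i4").tobytes()
        + samples.packed.tobytes()
    )
    bin_path = directory / "samples.bin"
    bin_path.write_bytes(payload)
    manifest = RunManifest(
        hyperparameters=asdict(samples.hyper),
        seed=samples.seed,
        n_regions=samples.n_regions,
        n_chains=int(len(np.unique(samples.chain_ids))),
        n_samples=n,
        acceptance_rates={str(k): v for k, v in (samples.acceptance_rates or {}).items()},
        software=f"bacon {__version__}",
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        checksum_sha256=hashlib.sha256(payload).hexdigest(),
    )
    manifest.save(directory / "manifest.json")
    return directory


def read_sample_archive(directory, n: Optional[int] = None):
    """Read a sample archive back into a GraphSampleSet.

    ``n`` limits the read to the first n samples.  The SHA-256 checksum
    in the manifest is always verified against the archive file.
    """
    from .sampler import GraphSampleSet  # deferred to avoid import cycle

    directory = Path(directory)
    payload = (directory / "samples.bin").read_bytes()
    manifest = RunManifest.load(directory / "manifest.json")
    if hashlib.sha256(payload).hexdigest() != manifest.checksum_sha256:
        raise ValueError(f"{directory}: archive checksum mismatch (corrupt archive)")
    if payload[:4] != _ARCHIVE_MAGIC:
        raise ValueError(f"{directory}: not a sample archive")
    if payload[4] != _ARCHIVE_VERSION:
        raise ValueError(f"{directory}: unsupported archive version {payload[4]}")
    K, n_total, nbytes = struct.unpack("<HIH", payload[5:13])
    off = 13
    chain_ids = np.frombuffer(payload, dtype="<i4", count=n_total, offset=off)
    off += 4 * n_total
    sweeps = np.frombuffer(payload, dtype="<i4", count=n_total, offset=off)
    off += 4 * n_total
    packed = np.frombuffer(payload, dtype=np.uint8, offset=off).reshape(
        n_total, nbytes
    )
    if n is not None:
        chain_ids, sweeps, packed = chain_ids[:n], sweeps[:n], packed[:n]
    return GraphSampleSet(
        packed=packed.copy(),
        n_regions=K,
        chain_ids=chain_ids.copy(),
        sweep_indices=sweeps.copy(),
        hyper=Hyperparameters(**manifest.hyperparameters),
        seed=manifest.seed,
        acceptance_rates={int(k): v for k, v in manifest.acceptance_rates.items()},
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

FIXTURE_PRESETS: dict[str, dict] = {
    "tiny": {"K": 4, "budget": 20},
    "small": {"K": 12, "budget": 1000},
    "medium": {"K": 30, "budget": 5000},
    "atlas_scale": {"K": 90, "budget": 5000},
}


def generate_fixture(
    preset: str, seed: int, budget: Optional[int] = None,
    hyper: Hyperparameters = Hyperparameters(),
):
    """Forward-simulate a named synthetic dataset with known ground truth.

    Presets: tiny (K=4, S=20, posterior enumerable over 64 graphs),
    small (K=12, S=1000), medium (K=30, S=5000) and atlas_scale (K=90, the 90-region atlas scale;
    budget configurable).  The ground-truth graph is a uniform random
    graph at the prior-mode density (0.2 for the default prior) so each
    preset's condition is exact, and counts are drawn from the
    generative model.

    Returns ``(adjacency, StreamlineCounts, manifest_dict)``.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(FIXTURE_PRESETS)}"
        )
    cfg = FIXTURE_PRESETS[preset]
    K = cfg["K"]
    S = budget if budget is not None else cfg["budget"]
    rng = np.random.default_rng(seed)
    e1 = int(round(n_pairs(K) * hyper.prior_density_mode()))
    truth = random_density_matched_graph(K, e1, rng)
    _, _, counts = forward_simulate(K, hyper, S, rng, graph=truth)
    manifest = {
        "preset": preset,
        "seed": int(seed),
        "n_regions": K,
        "streamline_budget": int(S),
        "hyperparameters": asdict(hyper),
        "true_edge_count": e1,
        "true_density": e1 / n_pairs(K),
    }
    return truth, counts, manifest
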