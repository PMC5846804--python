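"""Read/write connectivity stacks, matrices and phenotype tables.

All on-disk formats are plain delimited text (whitespace or comma), plus one
optional binary container (``.npz``) holding an ``m x N x N`` array with an
optional subject-ID sidecar.  Subject order is defined by lexical sort of
file stems in the directory layout and is preserved by every downstream
stage.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from conncluster.errors import DimensionError, StackError, TableError

_MATRIX_SUFFIXES = {".txt", ".csv", ".tsv", ".dat", ".mat"}


@dataclass
class ConnectomeStack:
    """m subject-labelled N x N connectivity matrices.

    Attributes
    ----------
    subjects : list of str
        Subject identifiers, in the order shared by every pipeline output.
    matrices : ndarray, shape (m, N, N)
        One square connectivity matrix per subject.
    node_labels : list of str, optional
        Names for the N nodes.
    """

    subjects: list[str]
    matrices: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3:
            raise StackError(
                f"expected an (m, N, N) array, got shape {self.matrices.shape}"
            )
        m, n1, n2 = self.matrices.shape
        if n1 != n2:
            raise DimensionError(f"matrices are {n1}x{n2}, not square")
        if m < 2 or n1 < 2:
            raise StackError(f"need m >= 2 subjects and N >= 2 nodes, got m={m}, N={n1}")
        if len(self.subjects) != m:
            raise StackError(
                f"{len(self.subjects)} subject IDs for {m} matrices"
            )
        if len(set(self.subjects)) != m:
            raise StackError("duplicate subject IDs")
        if not np.all(np.isfinite(self.matrices)):
            raise StackError("matrices contain non-finite entries")
        asym = np.max(np.abs(self.matrices - self.matrices.transpose(0, 2, 1)))
        if asym > 1e-8:
            warnings.warn(
                f"input matrices are asymmetric (max |A - A.T| = {asym:.3g}); "
                "proceeding anyway",
                stacklevel=2,
            )
        if self.node_labels is not None and len(self.node_labels) != n1:
            raise StackError(
                f"{len(self.node_labels)} node labels for N={n1} nodes"
            )

    @property
    def m(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass
class PhenotypeTable:
    """Per-subject behavioral/phenotypic variables (e.g., PANAS scores, age)."""

    subjects: list[str]
    data: pd.DataFrame = field(repr=False)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


def _load_text_matrix(path: Path) -> np.ndarray:
    """Load one whitespace- or comma-delimited matrix, with optional header."""
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DimensionError(f"{path}: empty file")
    # header detection: first line not parseable as floats
    normalized = [ln.replace(",", " ") for ln in lines]
    try:
        [float(tok) for tok in normalized[0].split()]
        body = normalized
    except ValueError:
        body = normalized[1:]
        # a labelled matrix also carries a leading ID column
        body = [" ".join(ln.split()[1:]) for ln in body]
    try:
        mat = np.loadtxt(_io.StringIO("\n".join(body)), ndmin=2)
    except ValueError as exc:
        raise DimensionError(f"{path}: could not parse matrix ({exc})") from exc
    return mat


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a single delimited-text matrix (header and label column allowed)."""
    return _load_text_matrix(Path(path))


def read_stack(path: str | Path, layout: str = "auto") -> ConnectomeStack:
    """Read a connectivity stack from a directory of matrices or one container.

    Parameters
    ----------
    path : path
        Directory of delimited-text matrices (subject ID = file stem, files
        sorted lexically) or a single ``.npz`` container with a ``matrices``
        array and optionally a ``subjects`` array.
    layout : {"auto", "directory", "container"}

    Returns
    -------
    ConnectomeStack
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if layout == "auto":
        layout = "directory" if path.is_dir() else "container"

    if layout == "directory":
        files = sorted(
            (p for p in path.iterdir()
             if p.is_file() and p.suffix.lower() in _MATRIX_SUFFIXES),
            key=lambda p: p.stem,
        )
        if len(files) < 2:
            raise StackError(f"{path}: need at least 2 matrix files, found {len(files)}")
        subjects, mats, dims = [], [], {}
        for f in files:
            mat = _load_text_matrix(f)
            if mat.shape[0] != mat.shape[1]:
                raise DimensionError(
                    f"{f.name}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square"
                )
            subjects.append(f.stem)
            mats.append(mat)
            dims.setdefault(mat.shape[0], []).append(f.name)
        if len(dims) > 1:
            detail = "; ".join(f"N={n}: {', '.join(names)}" for n, names in dims.items())
            raise StackError(f"inconsistent matrix dimensions across subjects: {detail}")
        return ConnectomeStack(subjects, np.stack(mats))

    if layout == "container":
        with np.load(path) as npz:
            if "matrices" not in npz:
                raise StackError(f"{path}: container lacks a 'matrices' array")
            mats = npz["matrices"]
            subjects = [str(s) for s in npz["subjects"]] if "subjects" in npz else None
        sidecar = path.with_suffix(path.suffix + ".subjects")
        if sidecar.exists():
            subjects = sidecar.read_text().split()
        if subjects is None:
            subjects = [f"sub{i:04d}" for i in range(mats.shape[0])]
        return ConnectomeStack(subjects, mats)

    raise ValueError(f"unknown layout {layout!r}")


def write_stack(stack: ConnectomeStack, path: str | Path) -> None:
    """Write a stack as an ``.npz`` container with subject IDs."""
    np.savez(Path(path), matrices=stack.matrices,
             subjects=np.array(stack.subjects))


def write_matrix(M: np.ndarray, path: str | Path,
                 labels: list[str] | None = None) -> None:
    """Write a square matrix as tab-delimited text, round-trippable to 1e-12.

    With ``labels``, a header row and a leading ID column are written.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise DimensionError("refusing to write an empty matrix")
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError(f"matrix of shape {M.shape} is not square")
    path = Path(path)
    with path.open("w") as fh:
        if labels is not None:
            if len(labels) != M.shape[0]:
                raise DimensionError(
                    f"{len(labels)} labels for a {M.shape[0]}x{M.shape[0]} matrix"
                )
            fh.write("id\t" + "\t".join(labels) + "\n")
            for lab, row in zip(labels, M):
                fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
        else:
            for row in M:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a delimited phenotype table; first column is the subject ID.

    Every non-ID column must parse as real-valued (empty cells become NaN);
    a column with text entries raises :class:`TableError` naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise TableError(f"{path}: need a subject-ID column plus >=1 variable")
    ids = df.iloc[:, 0].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise TableError(f"duplicate subject ID(s): {', '.join(dup)}")
    data = df.iloc[:, 1:].copy()
    for col in data.columns:
        try:
            data[col] = pd.to_numeric(data[col])
        except (ValueError, TypeError) as exc:
            raise TableError(
                f"column {col!r} is not real-valued: {exc}"
            ) from exc
    data.index = pd.Index(ids, name=df.columns[0])
    return PhenotypeTable(subjects=list(ids), data=data)
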