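"""Domain types and file I/O shared by the whole package.

The objects here mirror what a metabolite-identification workflow passes
around: MS/MS spectra as peak lists, molecular fingerprints as binary
vectors, candidate sets mapping each query spectrum to the molecules it
must be ranked against, and labelled Gram (kernel) matrices with
centering/normalization provenance.

File formats are deliberately plain text: MGF for spectra (with a
``GROUPID=`` header line carrying the molecular-structure group used for
cross-validation fold assignment), TSV/CSV for fingerprints, candidate
sets and kernel matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics.auxiliary import PyteomicsError

logger = logging.getLogger("iokr")

__all__ = [
    "Spectrum",
    "FingerprintTable",
    "CandidateSets",
    "KernelMatrix",
    "read_mgf",
    "write_mgf",
    "read_fingerprints",
    "write_fingerprints",
    "read_kernel_matrix",
    "write_kernel_matrix",
    "read_candidate_sets",
    "write_candidate_sets",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Spectrum


@dataclass
class Spectrum:
    """A tandem mass spectrum: an identifier plus a peak list.

    Parameters
    ----------
    id : str
        Unique spectrum identifier (MGF TITLE).
    group_id : str
        Molecular-structure identity; spectra of the same structure share a
        group and are kept in the same cross-validation fold.
    mz : array of float
        Peak mass-to-charge ratios in Da/charge, sorted ascending.
    intensity : array of float
        Nonnegative peak intensities (arbitrary units), aligned with ``mz``.
    precursor_mz : float, optional
    ionization_mode : {"positive", "negative", "unspecified"}
    """

    id: str
    group_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    ionization_mode: str = "unspecified"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError(f"spectrum {self.id!r}: mz/intensity shape mismatch")
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.id!r}: at least one peak required")
        if np.any(self.mz <= 0):
            raise ValueError(f"spectrum {self.id!r}: all m/z must be > 0")
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.id!r}: intensities must be >= 0")
        if self.ionization_mode not in ("positive", "negative", "unspecified"):
            raise ValueError(f"spectrum {self.id!r}: bad ionization mode")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


# ---------------------------------------------------------------------------
# FingerprintTable


@dataclass
class FingerprintTable:
    """Molecule id -> length-d binary fingerprint vector."""

    ids: list[str]
    d: int
    bits: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate molecule ids in fingerprint table")
        for mid in self.ids:
            v = np.asarray(self.bits[mid], dtype=np.uint8)
            if v.shape != (self.d,):
                raise ValueError(
                    f"fingerprint {mid!r} has {v.size} bits, expected {self.d}"
                )
            if not np.all((v == 0) | (v == 1)):
                raise ValueError(f"fingerprint {mid!r} contains non-binary values")
            self.bits[mid] = v

    def matrix(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Stack fingerprints (rows follow ``ids``) into an (n, d) array."""
        use = self.ids if ids is None else list(ids)
        missing = [m for m in use if m not in self.bits]
        if missing:
            raise KeyError(f"fingerprint(s) missing for id(s): {missing[:5]}")
        return np.stack([self.bits[m] for m in use]).astype(float)

    def subset(self, ids: Sequence[str]) -> "FingerprintTable":
        return FingerprintTable(list(ids), self.d, {m: self.bits[m] for m in ids})

    def add(self, mol_id: str, fp: np.ndarray) -> None:
        if mol_id in self.bits:
            raise ValueError(f"duplicate molecule id {mol_id!r}")
        v = np.asarray(fp, dtype=np.uint8)
        if v.shape != (self.d,) or not np.all((v == 0) | (v == 1)):
            raise ValueError(f"invalid fingerprint for {mol_id!r}")
        self.ids.append(mol_id)
        self.bits[mol_id] = v


# ---------------------------------------------------------------------------
# CandidateSets


@dataclass
class CandidateSets:
    """Per-query candidate molecule lists plus the identity of the truth.

    ``unrankable`` collects queries whose truth is absent from their own
    candidate list; they are excluded from accuracy denominators downstream.
    """

    candidates: dict[str, list[str]]
    truth: dict[str, str]
    unrankable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for q, cands in self.candidates.items():
            if q not in self.truth:
                raise ValueError(f"query {q!r} has no true molecule recorded")
            if self.truth[q] not in cands:
                logger.warning(
                    "query %s: true molecule %s not among its candidates; "
                    "flagged unrankable",
                    q,
                    self.truth[q],
                )
                self.unrankable.add(q)

    @property
    def query_ids(self) -> list[str]:
        return list(self.candidates)

    def all_candidate_ids(self, queries: Iterable[str] | None = None) -> list[str]:
        """Union of candidate ids over ``queries``, in first-seen order."""
        seen: dict[str, None] = {}
        for q in self.candidates if queries is None else queries:
            for c in self.candidates[q]:
                seen.setdefault(c, None)
        return list(seen)

    def validate_against(self, fps: FingerprintTable) -> None:
        for q, cands in self.candidates.items():
            for c in cands:
                if c not in fps.bits:
                    raise ValueError(f"candidate {c!r} of query {q!r} lacks a fingerprint")
            if self.truth[q] not in fps.bits:
                raise ValueError(f"truth {self.truth[q]!r} of query {q!r} lacks a fingerprint")


# ---------------------------------------------------------------------------
# KernelMatrix


@dataclass
class KernelMatrix:
    """A labelled Gram matrix (square) or cross-kernel matrix (rectangular).

    ``centered``/``normalized`` record the preprocessing already applied.
    ``row_self``/``col_self`` optionally carry per-point self-kernel values
    k(x, x) consistent with the matrix's preprocessing state; they are what a
    rectangular test-by-train matrix needs for cosine normalization.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    centered: bool = False
    normalized: bool = False
    row_self: np.ndarray | None = None
    col_self: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("kernel matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel matrix contains non-finite values")
        if self.is_square:
            scale = max(np.abs(self.values).max(), 1e-300)
            asym = np.abs(self.values - self.values.T).max()
            if asym > 1e-10 * scale:
                raise ValueError(
                    f"square kernel matrix asymmetric: max |K - K.T| = {asym:g}"
                )
            if self.normalized:
                dev = np.abs(np.diag(self.values) - 1.0).max()
                if dev > 1e-10:
                    raise ValueError(
                        f"normalized kernel diagonal deviates from 1 by {dev:g}"
                    )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# MGF I/O


def _unique_ids(raw_ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for rid in raw_ids:
        if rid not in seen:
            seen[rid] = 1
            out.append(rid)
        else:
            seen[rid] += 1
            new = f"{rid}_{seen[rid]}"
            logger.warning("duplicate spectrum id %r renamed to %r", rid, new)
            out.append(new)
    return out


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    TITLE is the spectrum id; an optional ``GROUPID=`` header carries the
    structure-group label (defaults to the id). Duplicate ids get ``_2``,
    ``_3``... suffixes with a logged warning. Malformed peak lines raise
    :class:`ParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: list[dict] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                raw.append(entry)
    except PyteomicsError as exc:
        msg = str(exc)
        lineno = None
        if "Line:" in msg:
            bad = msg.split("Line:", 1)[1].strip().splitlines()
            if bad:
                needle = bad[0].strip()
                for i, line in enumerate(path.read_text().splitlines(), start=1):
                    if line.strip() == needle:
                        lineno = i
                        break
        where = f" (line {lineno})" if lineno else ""
        raise ParseError(f"{path}: malformed MGF block{where}: {msg}") from exc
    if not raw:
        raise ParseError(f"{path}: no spectra found (empty or not MGF)")

    ids = _unique_ids([str(e["params"].get("title", f"spectrum_{i+1}"))
                       for i, e in enumerate(raw)])
    spectra = []
    for sid, entry in zip(ids, raw):
        params = entry["params"]
        pepmass = params.get("pepmass")
        precursor = None
        if pepmass is not None:
            precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
        mode = str(params.get("ionmode", "unspecified")).lower()
        if mode not in ("positive", "negative"):
            mode = "unspecified"
        spectra.append(
            Spectrum(
                id=sid,
                group_id=str(params.get("groupid", sid)),
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                precursor_mz=precursor,
                ionization_mode=mode,
            )
        )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF, one BEGIN IONS/END IONS block each, in order."""
    if not spectra:
        raise ValueError("refusing to write an empty spectrum list")
    entries = []
    for s in spectra:
        params: dict = {"title": s.id, "groupid": s.group_id}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.ionization_mode != "unspecified":
            params["ionmode"] = s.ionization_mode
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


# ---------------------------------------------------------------------------
# Fingerprints


def _sniff_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_fingerprints(path: str | Path) -> FingerprintTable:
    """Read a fingerprint table.

    Two dialects are accepted: a wide delimited table (header row; first
    column id, remaining columns 0/1) and a two-column form ``id<sep>bitstring``
    where the bitstring is a run of '0'/'1' characters.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ParseError(f"{path}: empty fingerprint file")
    sep = _sniff_sep(first)
    fields = first.rstrip("\n").split(sep)
    bitstring_dialect = (
        len(fields) == 2 and len(fields[1]) > 0 and set(fields[1]) <= {"0", "1"}
    )
    ids: list[str] = []
    bits: dict[str, np.ndarray] = {}
    if bitstring_dialect:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str)
        d = None
        for _, (mid, bstr) in df.iterrows():
            if not set(bstr) <= {"0", "1"}:
                raise ParseError(f"{path}: non-binary bitstring for id {mid!r}")
            v = np.frombuffer(bstr.encode(), dtype=np.uint8) - ord("0")
            if d is None:
                d = v.size
            elif v.size != d:
                raise ParseError(f"{path}: ragged row for id {mid!r}")
            if mid in bits:
                raise ParseError(f"{path}: duplicated id {mid!r}")
            ids.append(mid)
            bits[mid] = v
    else:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
        d = df.shape[1] - 1
        for row in df.itertuples(index=False):
            mid = str(row[0])
            vals = row[1:]
            if any(pd.isna(v) for v in vals):
                raise ParseError(f"{path}: ragged row for id {mid!r}")
            if any(str(v) not in ("0", "1") for v in vals):
                raise ParseError(f"{path}: non-binary cell for id {mid!r}")
            if mid in bits:
                raise ParseError(f"{path}: duplicated id {mid!r}")
            ids.append(mid)
            bits[mid] = np.array([int(v) for v in vals], dtype=np.uint8)
    if d is None or not ids:
        raise ParseError(f"{path}: no fingerprints found")
    return FingerprintTable(ids, int(d), bits)


def write_fingerprints(fps: FingerprintTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = "id\t" + "\t".join(f"b{j+1}" for j in range(fps.d))
        fh.write(header + "\n")
        for mid in fps.ids:
            fh.write(mid + "\t" + "\t".join(str(int(b)) for b in fps.bits[mid]) + "\n")


# ---------------------------------------------------------------------------
# Kernel matrices


def read_kernel_matrix(path: str | Path) -> KernelMatrix:
    """Read a TSV kernel matrix with a ``#centered=...;normalized=...`` header.

    Layout: optional '#' provenance line(s), then a header row of column ids
    (first cell empty or 'id'), then one row per row id. Absent provenance
    flags default to False.
    """
    path = Path(path)
    flags = {"centered": False, "normalized": False}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            for part in line[1:].strip().split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    if k.strip() in flags:
                        flags[k.strip()] = v.strip().lower() == "true"
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, header=0, index_col=0)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell in kernel matrix: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: non-finite value in kernel matrix")
    return KernelMatrix(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        values=values,
        centered=flags["centered"],
        normalized=flags["normalized"],
    )


def write_kernel_matrix(K: KernelMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#centered={str(K.centered).lower()};"
                 f"normalized={str(K.normalized).lower()}\n")
        fh.write("id\t" + "\t".join(K.col_ids) + "\n")
        for rid, row in zip(K.row_ids, K.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Candidate sets


def read_candidate_sets(path: str | Path) -> CandidateSets:
    """Read candidate sets from rows of ``query_id, candidate_id, is_true``.

    A header row is detected (third field not 0/1) and skipped. Exactly one
    is_true=1 row is required per query.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ParseError(f"{path}: empty candidate file")
    sep = _sniff_sep(first)
    header = 0 if first.rstrip("\n").split(sep)[-1].strip() not in ("0", "1") else None
    df = pd.read_csv(path, sep=sep, header=header, dtype=str)
    if df.shape[1] != 3:
        raise ParseError(f"{path}: expected 3 columns, got {df.shape[1]}")
    candidates: dict[str, list[str]] = {}
    truth: dict[str, str] = {}
    for q, c, flag in df.itertuples(index=False):
        q, c, flag = str(q), str(c), str(flag).strip()
        if flag not in ("0", "1"):
            raise ParseError(f"{path}: is_true flag {flag!r} for query {q!r}")
        candidates.setdefault(q, []).append(c)
        if flag == "1":
            if q in truth:
                raise ParseError(f"{path}: multiple true candidates for query {q!r}")
            truth[q] = c
    missing = [q for q in candidates if q not in truth]
    if missing:
        raise ParseError(f"{path}: no true candidate for query {missing[0]!r}")
    return CandidateSets(candidates, truth)


def write_candidate_sets(cands: CandidateSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcandidate_id\tis_true\n")
        for q, clist in cands.candidates.items():
            for c in clist:
                fh.write(f"{q}\t{c}\t{int(c == cands.truth[q])}\n")
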