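"""Diploid microsatellite genotype tables and the three interchange dialects.

Genotypes are unordered pairs of allele fragment sizes in base pairs,
canonicalized ascending. ``(0, 0)`` denotes a missing (untyped) call;
half-missing calls are rejected at parse time.

Three file dialects are supported explicitly (no sniffing):

``genalex``
    CSV with two count header rows, one column pair per locus.
``structure``
    One row per individual, two integer columns per locus, missing = -9.
    Allele sizes are recoded to small integers through a sidecar JSON
    dictionary written next to the main file (``<path>.meta.json``).
``genepop``
    Title line, one locus name per line, ``Pop`` separators, six-digit
    diploid codes (three digits per allele), missing = ``000000``. Group
    labels are carried in the title line as ``groups=a,b`` so that a
    round trip preserves them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = 0
STRUCTURE_MISSING = -9

Genotype = tuple[int, int]

DIALECTS = ("genalex", "structure", "genepop")


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.line = line


def canonical_genotype(a: int, b: int) -> Genotype:
    """Order a diploid call ascending; reject half-missing calls."""
    a, b = int(a), int(b)
    if a < 0 or b < 0:
        raise ValueError(f"negative allele size in call ({a}, {b})")
    if (a == MISSING) != (b == MISSING):
        raise ValueError(f"half-missing genotype ({a}, {b}) is not allowed")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus; only ``locus_id`` is carried by file dialects."""

    locus_id: str
    motif: str = ""
    unit_length: int | None = None
    cross_type: bool = True
    accession: str = ""
    size_range_by_type: dict | None = None

    def __post_init__(self):
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if self.unit_length is not None and self.unit_length not in (3, 4):
            raise ValueError(f"unit_length must be 3 or 4, got {self.unit_length}")


@dataclass(frozen=True)
class QCFlag:
    """A locus-level or call-level quality action.

    ``drop_locus`` removes the locus for every sample and never names a
    sample; ``zero_allele`` zeroes one sample's call and always names it.
    """

    locus_id: str
    issue: str  # single_locus_variant | non_amplifying | low_polymorphism
    action: str  # drop_locus | zero_allele | none
    sample_id: str | None = None

    _ISSUES = ("single_locus_variant", "non_amplifying", "low_polymorphism")
    _ACTIONS = ("drop_locus", "zero_allele", "none")

    def __post_init__(self):
        if self.issue not in self._ISSUES:
            raise ValueError(f"unknown issue {self.issue!r}")
        if self.action not in self._ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "drop_locus" and self.sample_id is not None:
            raise ValueError("drop_locus flags must not name a sample")
        if self.action == "zero_allele" and self.sample_id is None:
            raise ValueError("zero_allele flags must name a sample")


@dataclass
class SampleRecord:
    """One colony: id, mitochondrial-type label, and per-locus genotypes."""

    colony_id: str
    mito_type: str
    genotypes: dict[str, Genotype]
    population: str | None = None

    def __post_init__(self):
        if self.population is None:
            self.population = self.mito_type
        self.genotypes = {
            loc: canonical_genotype(*g) for loc, g in self.genotypes.items()
        }

    def genotype(self, locus_id: str) -> Genotype:
        return self.genotypes[locus_id]

    def is_missing(self, locus_id: str) -> bool:
        return self.genotypes[locus_id][0] == MISSING


@dataclass
class GenotypeMatrix:
    """Ordered samples x ordered loci; every sample carries every locus."""

    loci: list[LocusDef]
    samples: list[SampleRecord]

    def __post_init__(self):
        locus_ids = [l.locus_id for l in self.loci]
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids")
        sample_ids = [s.colony_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        for s in self.samples:
            missing = set(locus_ids) - set(s.genotypes)
            if missing:
                raise ValueError(
                    f"sample {s.colony_id} lacks genotype slots for {sorted(missing)}"
                )
            extra = set(s.genotypes) - set(locus_ids)
            if extra:
                raise ValueError(
                    f"sample {s.colony_id} has genotypes at unknown loci {sorted(extra)}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.colony_id for s in self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def mito_types(self) -> list[str]:
        """Distinct type labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.mito_type, None)
        return list(seen)

    def locus(self, locus_id: str) -> LocusDef:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def allele_array(self) -> np.ndarray:
        """(n_samples, n_loci, 2) int array of canonical allele sizes."""
        arr = np.zeros((self.n_samples, self.n_loci, 2), dtype=np.int64)
        for i, s in enumerate(self.samples):
            for j, lid in enumerate(self.locus_ids):
                arr[i, j, :] = s.genotypes[lid]
        return arr

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.locus_ids != other.locus_ids:
            return False
        if self.sample_ids != other.sample_ids:
            return False
        for a, b in zip(self.samples, other.samples):
            if a.mito_type != b.mito_type or a.genotypes != b.genotypes:
                return False
        return True

    # -- operations ------------------------------------------------------
    def subset(
        self,
        mito_type: str | None = None,
        locus_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to one mito type and/or a locus subset, order preserved."""
        if locus_ids is not None:
            unknown = set(locus_ids) - set(self.locus_ids)
            if unknown:
                raise KeyError(f"unknown loci requested: {sorted(unknown)}")
            keep = set(locus_ids)
            loci = [l for l in self.loci if l.locus_id in keep]
        else:
            loci = list(self.loci)
        if not loci:
            raise ValueError("subset selects zero loci")

        kept_ids = {l.locus_id for l in loci}
        samples = []
        for s in self.samples:
            if mito_type is not None and s.mito_type != mito_type:
                continue
            samples.append(
                SampleRecord(
                    colony_id=s.colony_id,
                    mito_type=s.mito_type,
                    population=s.population,
                    genotypes={k: v for k, v in s.genotypes.items() if k in kept_ids},
                )
            )
        if not samples:
            raise ValueError(f"subset selects zero samples (mito_type={mito_type!r})")
        return GenotypeMatrix(loci=loci, samples=samples)


def apply_locus_qc(matrix: GenotypeMatrix, flags: Iterable[QCFlag]) -> GenotypeMatrix:
    """Apply QC actions: drop whole loci or zero individual calls.

    Idempotent; independent flags commute. Flags with action ``none`` are
    recorded observations and change nothing.
    """
    flags = list(flags)
    known_loci = set(matrix.locus_ids)
    known_samples = set(matrix.sample_ids)
    for f in flags:
        if f.locus_id not in known_loci:
            raise KeyError(f"QC flag references unknown locus {f.locus_id!r}")
        if f.sample_id is not None and f.sample_id not in known_samples:
            raise KeyError(f"QC flag references unknown sample {f.sample_id!r}")

    drop = {f.locus_id for f in flags if f.action == "drop_locus"}
    zero = {(f.sample_id, f.locus_id) for f in flags if f.action == "zero_allele"}

    loci = [l for l in matrix.loci if l.locus_id not in drop]
    if not loci:
        raise ValueError("QC would drop every locus")
    kept = {l.locus_id for l in loci}
    samples = []
    for s in matrix.samples:
        geno = {}
        for lid, g in s.genotypes.items():
            if lid not in kept:
                continue
            geno[lid] = (MISSING, MISSING) if (s.colony_id, lid) in zero else g
        samples.append(
            SampleRecord(
                colony_id=s.colony_id,
                mito_type=s.mito_type,
                population=s.population,
                genotypes=geno,
            )
        )
    return GenotypeMatrix(loci=loci, samples=samples)


# ---------------------------------------------------------------------------
# dialect I/O
# ---------------------------------------------------------------------------

def read_genotype_table(path, dialect: str) -> GenotypeMatrix:
    """Read a genotype table in the named dialect (no format sniffing)."""
    path = Path(path)
    if dialect == "genalex":
        return _read_genalex(path)
    if dialect == "structure":
        return _read_structure(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_genotype_table(matrix: GenotypeMatrix, dialect: str, path) -> None:
    """Write ``matrix`` so that :func:`read_genotype_table` recovers it."""
    if matrix.n_loci == 0:
        raise ValueError("refusing to write a matrix with zero loci")
    if matrix.n_samples == 0:
        raise ValueError("refusing to write a matrix with zero samples")
    path = Path(path)
    if dialect == "genalex":
        _write_genalex(matrix, path)
    elif dialect == "structure":
        _write_structure(matrix, path)
    elif dialect == "genepop":
        _write_genepop(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _group_counts(matrix: GenotypeMatrix) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in matrix.samples:
        counts[s.mito_type] = counts.get(s.mito_type, 0) + 1
    return counts


def _parse_allele(token: str, path, lineno: int) -> int:
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        raise GenotypeParseError(
            f"non-integer allele value {token!r}", path, lineno
        ) from None


# -- GenAlEx ----------------------------------------------------------------

def _write_genalex(matrix: GenotypeMatrix, path: Path) -> None:
    counts = _group_counts(matrix)
    pops = list(counts)
    header1 = [str(matrix.n_loci), str(matrix.n_samples), str(len(pops))]
    header1 += [str(counts[p]) for p in pops]
    header2 = ["msatpop export", "", ""] + pops
    header3 = ["Sample", "Pop"]
    for lid in matrix.locus_ids:
        header3 += [lid, ""]
    lines = [",".join(header1), ",".join(header2), ",".join(header3)]
    for s in matrix.samples:
        row = [s.colony_id, s.mito_type]
        for lid in matrix.locus_ids:
            a, b = s.genotypes[lid]
            row += [str(a), str(b)]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_genalex(path: Path) -> GenotypeMatrix:
    raw = path.read_text().splitlines()
    if len(raw) < 4:
        raise GenotypeParseError("file too short for genalex dialect", path, len(raw))
    try:
        h1 = [t for t in raw[0].split(",")]
        n_loci = int(h1[0])
        n_samples = int(h1[1])
    except (ValueError, IndexError):
        raise GenotypeParseError("bad count header", path, 1) from None
    h3 = raw[2].split(",")
    if len(h3) < 2 + 2 * n_loci:
        raise GenotypeParseError(
            f"locus header has {len(h3)} columns, need {2 + 2 * n_loci}", path, 3
        )
    locus_ids = [h3[2 + 2 * j].strip() for j in range(n_loci)]
    if any(not lid for lid in locus_ids):
        raise GenotypeParseError("empty locus name in header", path, 3)

    samples = []
    for lineno, line in enumerate(raw[3:], start=4):
        if not line.strip():
            continue
        row = line.split(",")
        if len(row) < 2 + 2 * n_loci:
            raise GenotypeParseError(
                f"row has {len(row)} columns, need {2 + 2 * n_loci}", path, lineno
            )
        geno = {}
        for j, lid in enumerate(locus_ids):
            a = _parse_allele(row[2 + 2 * j], path, lineno)
            b = _parse_allele(row[3 + 2 * j], path, lineno)
            try:
                geno[lid] = canonical_genotype(a, b)
            except ValueError as e:
                raise GenotypeParseError(str(e), path, lineno) from None
        samples.append(
            SampleRecord(colony_id=row[0].strip(), mito_type=row[1].strip(), genotypes=geno)
        )
    if len(samples) != n_samples:
        raise GenotypeParseError(
            f"header declares {n_samples} samples but {len(samples)} rows found",
            path,
            len(raw),
        )
    return GenotypeMatrix(loci=[LocusDef(lid) for lid in locus_ids], samples=samples)


# -- STRUCTURE --------------------------------------------------------------

def _write_structure(matrix: GenotypeMatrix, path: Path) -> None:
    # per-locus dictionaries: sorted unique nonzero sizes -> 1..k
    allele_codes: dict[str, dict[int, int]] = {}
    for lid in matrix.locus_ids:
        sizes = sorted(
            {a for s in matrix.samples for a in s.genotypes[lid] if a != MISSING}
        )
        allele_codes[lid] = {size: i + 1 for i, size in enumerate(sizes)}
    pops = matrix.mito_types
    pop_codes = {p: i + 1 for i, p in enumerate(pops)}

    lines = [" ".join(matrix.locus_ids)]
    for s in matrix.samples:
        row = [s.colony_id, str(pop_codes[s.mito_type])]
        for lid in matrix.locus_ids:
            for a in s.genotypes[lid]:
                row.append(
                    str(STRUCTURE_MISSING) if a == MISSING else str(allele_codes[lid][a])
                )
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")

    meta = {
        "pops": {str(code): label for label, code in pop_codes.items()},
        "alleles": {
            lid: {str(code): size for size, code in codes.items()}
            for lid, codes in allele_codes.items()
        },
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _read_structure(path: Path) -> GenotypeMatrix:
    raw = [l for l in path.read_text().splitlines()]
    if not raw or not raw[0].strip():
        raise GenotypeParseError("missing locus header line", path, 1)
    locus_ids = raw[0].split()
    n_loci = len(locus_ids)

    meta_path = Path(str(path) + ".meta.json")
    pops_map: dict[str, str] = {}
    allele_map: dict[str, dict[str, int]] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        pops_map = meta.get("pops", {})
        allele_map = meta.get("alleles", {})

    samples = []
    for lineno, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        row = line.split()
        if len(row) != 2 + 2 * n_loci:
            raise GenotypeParseError(
                f"row has {len(row)} fields, need {2 + 2 * n_loci}", path, lineno
            )
        pop_token = row[1]
        mito = pops_map.get(pop_token, pop_token)
        geno = {}
        for j, lid in enumerate(locus_ids):
            pair = []
            for tok in (row[2 + 2 * j], row[3 + 2 * j]):
                code = _parse_allele(tok, path, lineno)
                if code == STRUCTURE_MISSING:
                    pair.append(MISSING)
                elif lid in allele_map:
                    try:
                        pair.append(allele_map[lid][str(code)])
                    except KeyError:
                        raise GenotypeParseError(
                            f"allele code {code} absent from dictionary for {lid}",
                            path,
                            lineno,
                        ) from None
                else:
                    pair.append(code)
            try:
                geno[lid] = canonical_genotype(*pair)
            except ValueError as e:
                raise GenotypeParseError(str(e), path, lineno) from None
        samples.append(SampleRecord(colony_id=row[0], mito_type=mito, genotypes=geno))
    if not samples:
        raise GenotypeParseError("no data rows", path, len(raw))
    return GenotypeMatrix(loci=[LocusDef(lid) for lid in locus_ids], samples=samples)


# -- Genepop ----------------------------------------------------------------

def _write_genepop(matrix: GenotypeMatrix, path: Path) -> None:
    for s in matrix.samples:
        for lid, (a, b) in s.genotypes.items():
            if a > 999 or b > 999:
                raise ValueError(
                    f"allele size > 999 bp at {s.colony_id}/{lid} cannot be "
                    "encoded as a 3-digit genepop code"
                )
    pops = matrix.mito_types
    lines = ["msatpop genepop export groups=" + ",".join(pops)]
    lines += matrix.locus_ids
    for pop in pops:
        lines.append("Pop")
        for s in matrix.samples:
            if s.mito_type != pop:
                continue
            codes = [
                f"{a:03d}{b:03d}"
                for a, b in (s.genotypes[lid] for lid in matrix.locus_ids)
            ]
            lines.append(f"{s.colony_id} , " + " ".join(codes))
    path.write_text("\n".join(lines) + "\n")


def _read_genepop(path: Path) -> GenotypeMatrix:
    raw = path.read_text().splitlines()
    if len(raw) < 3:
        raise GenotypeParseError("file too short for genepop dialect", path, len(raw))
    title = raw[0]
    m = re.search(r"groups=(\S+)", title)
    group_labels = m.group(1).split(",") if m else []

    locus_ids: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        line = raw[i].strip()
        if line:
            # locus lines may be comma-separated lists
            locus_ids.extend(t.strip() for t in line.split(",") if t.strip())
        i += 1
    if i == len(raw):
        raise GenotypeParseError("no 'Pop' separator found", path, len(raw))
    if not locus_ids:
        raise GenotypeParseError("no locus names before first 'Pop'", path, i + 1)

    samples = []
    pop_idx = -1
    for lineno in range(i, len(raw)):
        line = raw[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenotypeParseError("sample line lacks ',' separator", path, lineno + 1)
        sid, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_ids):
            raise GenotypeParseError(
                f"{len(tokens)} genotype fields for {len(locus_ids)} loci",
                path,
                lineno + 1,
            )
        label = (
            group_labels[pop_idx]
            if pop_idx < len(group_labels)
            else f"Pop{pop_idx + 1}"
        )
        geno = {}
        for lid, tok in zip(locus_ids, tokens):
            if len(tok) != 6 or not tok.isdigit():
                raise GenotypeParseError(
                    f"genotype code {tok!r} is not a 6-digit field", path, lineno + 1
                )
            try:
                geno[lid] = canonical_genotype(int(tok[:3]), int(tok[3:]))
            except ValueError as e:
                raise GenotypeParseError(str(e), path, lineno + 1) from None
        samples.append(
            SampleRecord(colony_id=sid.strip(), mito_type=label, genotypes=geno)
        )
    if not samples:
        raise GenotypeParseError("no sample rows", path, len(raw))
    return GenotypeMatrix(loci=[LocusDef(lid) for lid in locus_ids], samples=samples)
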