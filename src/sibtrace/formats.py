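"""On-disk formats and core in-memory containers.

Handles the three text formats the pipeline touches: EIGENSTRAT genotype
triplets (``.geno``/``.snp``/``.ind``), samtools-style pileup text, and
IntCal-style radiocarbon calibration curves.  All coordinates are 1-based;
genetic positions are stored in Morgans.

Conventions
-----------
* A genotype value counts copies of *allele1* (the 5th ``.snp`` column);
  ``9`` encodes missing, both on disk and in memory.
* Chromosomes are integers with X = 23 and Y = 24 (EIGENSTRAT convention);
  mitochondrial and unplaced contigs are rejected.
* Pseudohaploid individuals carry only calls in ``{0, 2, 9}``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

MISSING = 9
X_CHROM = 23
Y_CHROM = 24

_CHROM_ALIASES = {"X": X_CHROM, "Y": Y_CHROM, "23": X_CHROM, "24": Y_CHROM}


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# SnpPanel
# ---------------------------------------------------------------------------

@dataclass
class SnpPanel:
    """Ordered site list with alleles and physical/genetic positions."""

    ids: np.ndarray          # str
    chrom: np.ndarray        # int, 1..22 autosomes, 23=X, 24=Y
    gpos: np.ndarray         # float, Morgans
    ppos: np.ndarray         # int, 1-based
    allele1: np.ndarray      # str, single base
    allele2: np.ndarray      # str, single base

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.gpos = np.asarray(self.gpos, dtype=np.float64)
        self.ppos = np.asarray(self.ppos, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        n = len(self.ids)
        for name in ("chrom", "gpos", "ppos", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel column {name!r} has wrong length")
        if n:
            order = np.lexsort((self.ppos, self.chrom))
            if not np.array_equal(order, np.arange(n)):
                raise ValueError("panel sites must be sorted by (chromosome, physical position)")
            key = self.chrom * (self.ppos.max() + 1) + self.ppos
            if len(np.unique(key)) != n:
                raise ValueError("duplicate (chromosome, physical position) in panel")
            for c in np.unique(self.chrom):
                g = self.gpos[self.chrom == c]
                if np.any(np.diff(g) < 0):
                    raise ValueError(f"genetic positions decrease within chromosome {c}")
            if np.any(self.gpos < 0):
                raise ValueError("negative genetic position")
            if np.any(self.allele1 == self.allele2):
                raise ValueError("allele1 == allele2 at some site")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.ids)

    def is_autosomal(self) -> np.ndarray:
        return (self.chrom >= 1) & (self.chrom <= 22)

    def site_index(self) -> dict[tuple[int, int], int]:
        """Map (chromosome, physical position) -> row index."""
        return {(int(c), int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.ppos))}

    def subset(self, mask: np.ndarray) -> "SnpPanel":
        return SnpPanel(self.ids[mask], self.chrom[mask], self.gpos[mask],
                        self.ppos[mask], self.allele1[mask], self.allele2[mask])


@dataclass
class Individual:
    id: str
    population: str
    sex: str = "U"                    # M / F / U
    ploidy_mode: str = "diploid"      # diploid / pseudohaploid


@dataclass
class GenotypeMatrix:
    """Individuals x sites calls in {0, 1, 2, 9(=missing)} counting allele1."""

    panel: SnpPanel
    individuals: list[Individual]
    calls: np.ndarray                 # int8, shape (n_ind, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.panel)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.panel)} sites")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid call {self.calls[i, j]} at individual {i}, site {j}")
        for i, ind in enumerate(self.individuals):
            if ind.ploidy_mode == "pseudohaploid" and np.any(self.calls[i] == 1):
                raise ValueError(f"pseudohaploid individual {ind.id!r} has a heterozygous call")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.array([i for i, ind in enumerate(self.individuals)
                        if ind.population == population], dtype=np.int64)
        if idx.size == 0:
            raise KeyError(f"no individuals in population {population!r}")
        return idx


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def _parse_chrom(token: str, path: str, lineno: int) -> int:
    tok = token.upper()
    if tok in _CHROM_ALIASES:
        return _CHROM_ALIASES[tok]
    try:
        c = int(tok)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: unsupported chromosome {token!r}")
    if not 1 <= c <= 24:
        raise FormatError(f"{path}:{lineno}: chromosome {token!r} outside 1-24")
    return c


def read_snp(path: str | Path) -> SnpPanel:
    ids, chrom, gpos, ppos, a1, a2 = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            ids.append(fields[0])
            chrom.append(_parse_chrom(fields[1], str(path), lineno))
            gpos.append(float(fields[2]))
            ppos.append(int(fields[3]))
            a1.append(fields[4])
            a2.append(fields[5])
    return SnpPanel(np.array(ids, dtype=object), chrom, gpos, ppos,
                    np.array(a1, dtype=object), np.array(a2, dtype=object))


def read_ind(path: str | Path) -> list[Individual]:
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            sex = fields[1].upper()
            if sex not in ("M", "F", "U"):
                raise FormatError(f"{path}:{lineno}: sex must be M/F/U, got {fields[1]!r}")
            individuals.append(Individual(id=fields[0], population=fields[2], sex=sex))
    return individuals


def read_eigenstrat(prefix: str | Path | None = None, *,
                    geno: str | Path | None = None,
                    snp: str | Path | None = None,
                    ind: str | Path | None = None,
                    ploidy_overrides: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a geno/snp/ind triplet.

    Individuals with no heterozygous call are flagged pseudohaploid unless
    ``ploidy_overrides`` maps their id to an explicit mode.
    """
    if prefix is not None:
        geno = geno or f"{prefix}.geno"
        snp = snp or f"{prefix}.snp"
        ind = ind or f"{prefix}.ind"
    if geno is None or snp is None or ind is None:
        raise ValueError("need a prefix or all of geno/snp/ind paths")
    panel = read_snp(snp)
    individuals = read_ind(ind)
    n_ind = len(individuals)
    if n_ind == 0:
        return GenotypeMatrix(panel, [], np.zeros((0, len(panel)), dtype=np.int8))
    rows = []
    with open(geno) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if len(line) != n_ind:
                raise FormatError(
                    f"{geno}:{lineno}: row length {len(line)} != {n_ind} individuals")
            bad = re.search(r"[^0129]", line)
            if bad:
                raise FormatError(
                    f"{geno}:{lineno}: invalid character {bad.group()!r} at column {bad.start() + 1}")
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(rows) != len(panel):
        raise FormatError(f"{geno}: {len(rows)} genotype rows but {len(panel)} panel sites")
    calls = (np.array(rows, dtype=np.int8).T if rows
             else np.zeros((n_ind, 0), dtype=np.int8))
    ploidy_overrides = ploidy_overrides or {}
    for i, indiv in enumerate(individuals):
        if indiv.id in ploidy_overrides:
            indiv.ploidy_mode = ploidy_overrides[indiv.id]
        elif calls.shape[1] and not np.any(calls[i] == 1):
            indiv.ploidy_mode = "pseudohaploid"
    return GenotypeMatrix(panel, individuals, calls)


def write_eigenstrat(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a canonical geno/snp/ind triplet (single-space columns)."""
    panel = matrix.panel
    with open(f"{prefix}.snp", "w") as fh:
        for i in range(len(panel)):
            fh.write(f"{panel.ids[i]} {panel.chrom[i]} {panel.gpos[i]:.6f} "
                     f"{panel.ppos[i]} {panel.allele1[i]} {panel.allele2[i]}\n")
    with open(f"{prefix}.ind", "w") as fh:
        for ind in matrix.individuals:
            fh.write(f"{ind.id} {ind.sex} {ind.population}\n")
    digits = np.array([str(d) for d in range(10)], dtype=object)
    with open(f"{prefix}.geno", "w") as fh:
        if matrix.individuals:
            for j in range(len(panel)):
                fh.write("".join(digits[matrix.calls[:, j]]) + "\n")


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class Observation:
    base: str                         # A/C/G/T/N, reference strand orientation
    base_quality: int
    mapping_quality: int
    read_position: int = -1           # 0-based offset from the read's 5' end; -1 unknown
    read_length: int = -1
    strand: str = "+"


@dataclass
class PileupSite:
    chrom: int
    ppos: int
    ref: str
    observations: list[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


_INDEL_RE = re.compile(r"[+-](\d+)")


def _parse_bases(bases: str, ref: str, path: str, lineno: int) -> list[tuple[str, str]]:
    """Expand a pileup base string into (base, strand) pairs, skipping indels."""
    out: list[tuple[str, str]] = []
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":                 # read start; next char is mapping quality
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise FormatError(f"{path}:{lineno}: malformed indel at column {i + 1}")
            length = int(m.group(1))
            i = m.end() + length
            continue
        if ch == ".":
            out.append((ref.upper(), "+"))
        elif ch == ",":
            out.append((ref.upper(), "-"))
        elif ch in "ACGTN":
            out.append((ch, "+"))
        elif ch in "acgtn":
            out.append((ch.upper(), "-"))
        elif ch in "*><":             # deletion placeholder / ref skip: no base observed
            out.append(("", "+"))
        else:
            raise FormatError(f"{path}:{lineno}: unexpected pileup character {ch!r}")
        i += 1
    return out


def read_pileup(source: str | Path | TextIO, panel: SnpPanel, *,
                with_mapping_quality: bool = True) -> Iterator[PileupSite]:
    """Parse pileup text, keeping only sites present in ``panel``.

    Expected columns: chrom, pos, ref, depth, bases, base-quals and, when
    ``with_mapping_quality`` is set, a 7th column of phred+33 mapping
    qualities.  Two further optional columns carry comma-separated read
    positions (0-based from the 5' end) and read lengths, as emitted by
    :func:`sibtrace.synthetic.write_pileup`.
    """
    close = False
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source)
        close = True
        name = str(source)
    else:
        fh = source
        name = getattr(source, "name", "<stream>")
    index = panel.site_index()
    try:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{name}:{lineno}: expected >= 6 tab-separated columns")
            chrom = _parse_chrom(fields[0], name, lineno)
            ppos = int(fields[1])
            if (chrom, ppos) not in index:
                continue
            ref = fields[2].upper()
            pairs = _parse_bases(fields[4], ref, name, lineno)
            quals = fields[5]
            if len(pairs) != len(quals):
                raise FormatError(
                    f"{name}:{lineno}: {len(pairs)} bases but {len(quals)} base qualities")
            col = 6
            if with_mapping_quality:
                if len(fields) <= col:
                    raise FormatError(f"{name}:{lineno}: mapping-quality column missing")
                mquals = fields[col]
                if len(mquals) != len(pairs):
                    raise FormatError(
                        f"{name}:{lineno}: {len(pairs)} bases but {len(mquals)} mapping qualities")
                col += 1
            else:
                mquals = None
            rpos = rlen = None
            if len(fields) > col and fields[col]:
                rpos = [int(x) for x in fields[col].split(",")]
                if len(rpos) != len(pairs):
                    raise FormatError(f"{name}:{lineno}: read-position count mismatch")
            col += 1
            if len(fields) > col and fields[col]:
                rlen = [int(x) for x in fields[col].split(",")]
                if len(rlen) != len(pairs):
                    raise FormatError(f"{name}:{lineno}: read-length count mismatch")
            obs = []
            for k, (base, strand) in enumerate(pairs):
                if not base:          # deletion placeholder
                    continue
                obs.append(Observation(
                    base=base,
                    base_quality=ord(quals[k]) - 33,
                    mapping_quality=(ord(mquals[k]) - 33) if mquals else 255,
                    read_position=rpos[k] if rpos else -1,
                    read_length=rlen[k] if rlen else -1,
                    strand=strand))
            yield PileupSite(chrom=chrom, ppos=ppos, ref=ref, observations=obs)
    finally:
        if close:
            fh.close()


def write_pileup(sites: Iterable[PileupSite], dest: str | Path | TextIO) -> None:
    """Write sites in the extended dialect read_pileup understands."""
    close = False
    if isinstance(dest, (str, Path)):
        fh: TextIO = open(dest, "w")
        close = True
    else:
        fh = dest
    try:
        for site in sites:
            bases, bq, mq, rp, rl = [], [], [], [], []
            for o in site.observations:
                if o.base == site.ref and o.strand == "+":
                    bases.append(".")
                elif o.base == site.ref:
                    bases.append(",")
                else:
                    bases.append(o.base if o.strand == "+" else o.base.lower())
                bq.append(chr(min(o.base_quality, 93) + 33))
                mq.append(chr(min(o.mapping_quality, 93) + 33))
                rp.append(str(o.read_position))
                rl.append(str(o.read_length))
            fh.write("\t".join([
                str(site.chrom), str(site.ppos), site.ref, str(site.depth),
                "".join(bases) or "*", "".join(bq) or "*", "".join(mq) or "*",
                ",".join(rp), ",".join(rl)]) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------

@dataclass
class CalCurve:
    """Radiocarbon calibration curve: calendar age vs conventional 14C age.

    Rows are stored ascending in calendar age; evaluation interpolates
    linearly between rows.
    """

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=np.float64)
        self.c14_bp = np.asarray(self.c14_bp, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if len(self.cal_bp) < 2:
            raise ValueError("calibration curve needs at least 2 rows")
        order = np.argsort(self.cal_bp)
        self.cal_bp = self.cal_bp[order]
        self.c14_bp = self.c14_bp[order]
        self.sigma = self.sigma[order]
        if np.any(np.diff(self.cal_bp) <= 0):
            raise FormatError("calibration curve calendar ages are not strictly monotone")
        if np.any(self.sigma <= 0):
            raise ValueError("calibration curve sigma must be positive")

    def mu(self, theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, self.cal_bp, self.c14_bp)

    def sigma_at(self, theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, self.cal_bp, self.sigma)


def read_calcurve(path: str | Path) -> CalCurve:
    """Read an IntCal-style ``.14c`` table (comma or whitespace separated).

    Lines starting with ``#`` are headers; the first three columns are
    calBP, 14C age BP and the curve's one-sigma error.  Decreasing calBP
    order (the published convention) is accepted and re-sorted.
    """
    cal, c14, sig = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in re.split(r"[,\s]+", line) if f]
            if len(fields) < 3:
                raise FormatError(f"{path}: expected >= 3 columns, got {line!r}")
            cal.append(float(fields[0]))
            c14.append(float(fields[1]))
            sig.append(float(fields[2]))
    return CalCurve(np.array(cal), np.array(c14), np.array(sig))
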