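"""Genotype containers and plain-text I/O.

The central object is :class:`GenotypeMatrix`: individuals x biallelic SNPs,
dosage-coded 0/1/2 with a reserved missing sentinel.  Two text formats are
supported: PLINK PED/MAP pairs and a simple tab-delimited dosage table with an
optional label column.  Dosages always count the MINOR allele, recomputed from
the data at hand (ties broken by lexicographic order of the allele symbol), so
files from different sources land on one coding convention.

SNP indices are 0-based throughout; windows are half-open ``[start, start+len)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Sentinel for a missing genotype call (distinct from valid dosages 0/1/2).
MISSING: int = -1


class GenotypeError(ValueError):
    """Invalid genotype data or metadata."""


class ParseError(GenotypeError):
    """Malformed input file; message carries row/column coordinates."""


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP.  ``allele_a`` is the counted (minor) allele."""

    snp_id: str
    chromosome: str
    position: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise GenotypeError("SNP id must be non-empty")
        if self.position <= 0:
            raise GenotypeError(f"SNP {self.snp_id}: position must be positive")
        if self.allele_a == self.allele_b and self.allele_a != "0":
            raise GenotypeError(f"SNP {self.snp_id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """M individuals x N SNPs dosage matrix with metadata.

    ``dosages`` is an integer array with entries in {0, 1, 2} or
    :data:`MISSING`.  Rows follow ``sample_ids``, columns follow ``snps``.
    """

    sample_ids: list[str]
    snps: list[SNPRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be 2-dimensional")
        m, n = self.dosages.shape
        if m != len(self.sample_ids):
            raise GenotypeError(
                f"row count {m} != number of sample ids {len(self.sample_ids)}"
            )
        if n != len(self.snps):
            raise GenotypeError(f"column count {n} != number of SNPs {len(self.snps)}")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise GenotypeError(
                f"invalid dosage {self.dosages[tuple(bad)]} at row {bad[0]}, col {bad[1]}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING


@dataclass
class LabelSet:
    """Two-class population labels keyed by sample id.

    ``labels`` maps sample id -> class index in {0, 1}; ``class_names`` gives
    the human-readable name per class.
    """

    labels: dict[str, int]
    class_names: tuple[str, str] = ("class0", "class1")

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {0, 1}
        if bad:
            raise GenotypeError(f"labels must be 0/1, got {sorted(bad)}")

    def y_for(self, gm: GenotypeMatrix) -> np.ndarray:
        """Class vector aligned with ``gm`` rows; -1 where unlabelled."""
        return np.array([self.labels.get(s, -1) for s in gm.sample_ids], dtype=int)

    def class_counts(self) -> tuple[int, int]:
        vals = list(self.labels.values())
        return vals.count(0), vals.count(1)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = set(self.labels) - set(gm.sample_ids)
        if missing:
            raise GenotypeError(f"labelled ids absent from matrix: {sorted(missing)[:5]}")
        c0, c1 = self.class_counts()
        if c0 < 2 or c1 < 2:
            raise GenotypeError(f"each class needs >= 2 members (got {c0}, {c1})")


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    Dosage is the count of the minor allele, with the minor allele determined
    from the file's own allele frequencies (lexicographically smaller symbol on
    an exact tie).  A ``0 0`` allele pair is a missing call.
    """
    snps_meta: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 MAP columns")
            chrom, snp_id, _gdist, pos = parts[0], parts[1], parts[2], parts[3]
            snps_meta.append((snp_id, chrom, int(pos)))
    n = len(snps_meta)

    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n:
                raise ParseError(
                    f"{ped_path}: row {lineno}: expected {6 + 2 * n} columns "
                    f"(6 + 2x{n} SNPs), got {len(parts)}"
                )
            sample_ids.append(parts[1])
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n)]
            allele_rows.append(pairs)

    m = len(sample_ids)
    dosages = np.full((m, n), MISSING, dtype=np.int8)
    snps: list[SNPRecord] = []
    for j, (snp_id, chrom, pos) in enumerate(snps_meta):
        counts: dict[str, int] = {}
        for i in range(m):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                if a1 != a2:
                    raise ParseError(
                        f"{ped_path}: row {i + 1}, SNP {snp_id}: half-missing call"
                    )
                continue
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
        if len(counts) > 2:
            raise GenotypeError(
                f"SNP {snp_id}: more than two alleles observed: {sorted(counts)}"
            )
        if len(counts) == 2:
            # minor = lower frequency; lexicographic tie-break
            (s1, c1), (s2, c2) = sorted(counts.items())
            minor, major = (s1, s2) if (c1, s1) <= (c2, s2) else (s2, s1)
        elif len(counts) == 1:
            # fixed site: the single observed allele is major, minor unknown
            major, minor = next(iter(counts)), "0"
        else:
            major, minor = "0", "0"
        snps.append(SNPRecord(snp_id, chrom, pos, allele_a=minor, allele_b=major))
        for i in range(m):
            a1, a2 = allele_rows[i][j]
            if a1 == "0":
                continue
            dosages[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeMatrix(sample_ids, snps, dosages)


def write_ped_map(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a PED/MAP pair.  ``allele_a`` (counted) must be set per SNP."""
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    geno = {
        2: lambda s: f"{s.allele_a} {s.allele_a}",
        1: lambda s: f"{s.allele_a} {s.allele_b}",
        0: lambda s: f"{s.allele_b} {s.allele_b}",
        MISSING: lambda s: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, s in enumerate(gm.snps):
                d = int(gm.dosages[i, j])
                if d > 0 and s.allele_a == "0":
                    raise GenotypeError(
                        f"SNP {s.snp_id}: cannot write dosage {d} without a minor allele symbol"
                    )
                fields.append(geno[d](s))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Dosage table (TSV)
# ---------------------------------------------------------------------------

_DOSAGE_TOKENS = {"0": 0, "1": 1, "2": 2, "NA": MISSING}


def read_dosage_table(path: str | Path) -> tuple[GenotypeMatrix, LabelSet | None]:
    """Read a tab-delimited dosage table.

    Layout: optional ``#`` comment lines, then a header row
    ``sample_id [label] snp1 snp2 ...`` and one row per sample with dosage
    tokens in {0,1,2,NA}.  Returns the matrix plus a :class:`LabelSet` when a
    ``label`` column is present.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty table")
    header = lines[0].split("\t")
    has_label = len(header) > 1 and header[1].lower() == "label"
    first_data = 2 if has_label else 1
    snp_ids = header[first_data:]
    snps = [
        SNPRecord(sid, "1", j + 1, allele_a="A", allele_b="B")
        for j, sid in enumerate(snp_ids)
    ]
    n = len(snp_ids)

    sample_ids: list[str] = []
    raw_labels: list[str] = []
    rows: list[list[int]] = []
    for r, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != first_data + n:
            raise ParseError(
                f"{path}: row {r}: expected {first_data + n} columns, got {len(parts)}"
            )
        sample_ids.append(parts[0])
        if has_label:
            raw_labels.append(parts[1])
        vals = []
        for c, tok in enumerate(parts[first_data:], start=first_data + 1):
            try:
                vals.append(_DOSAGE_TOKENS[tok])
            except KeyError:
                raise ParseError(
                    f"{path}: row {r}, column {c}: invalid dosage token {tok!r}"
                ) from None
        rows.append(vals)

    gm = GenotypeMatrix(sample_ids, snps, np.array(rows, dtype=np.int8))
    labels: LabelSet | None = None
    if has_label:
        classes = sorted(set(raw_labels))
        if len(classes) != 2:
            raise ParseError(f"{path}: label column must have exactly 2 classes, got {classes}")
        mapping = {name: k for k, name in enumerate(classes)}
        labels = LabelSet(
            {sid: mapping[lab] for sid, lab in zip(sample_ids, raw_labels)},
            class_names=(classes[0], classes[1]),
        )
    return gm, labels


def write_dosage_table(
    gm: GenotypeMatrix,
    path: str | Path,
    labels: LabelSet | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a dosage table; byte-stable for a fixed matrix/labels ordering."""
    inv = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        cols = ["sample_id"]
        if labels is not None:
            cols.append("label")
        cols += [s.snp_id for s in gm.snps]
        fh.write("\t".join(cols) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid]
            if labels is not None:
                fields.append(labels.class_names[labels.labels[sid]])
            fields += [inv[int(d)] for d in gm.dosages[i]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Windowing and imputation
# ---------------------------------------------------------------------------

def subset_window(gm: GenotypeMatrix, start_index: int, length: int) -> GenotypeMatrix:
    """Contiguous SNP slice ``[start_index, start_index + length)``."""
    if start_index < 0 or length < 0 or start_index + length > gm.n_snps:
        raise GenotypeError(
            f"window [{start_index}, {start_index + length}) out of range for N={gm.n_snps}"
        )
    return GenotypeMatrix(
        list(gm.sample_ids),
        gm.snps[start_index : start_index + length],
        gm.dosages[:, start_index : start_index + length].copy(),
    )


def window_ranges(n_snps: int, window_size: int) -> list[tuple[int, int]]:
    """Non-overlapping full windows tiling the SNP axis; a trailing partial
    window is dropped (fixed-size windows only)."""
    if window_size <= 0 or window_size > n_snps:
        raise GenotypeError(f"window size {window_size} invalid for N={n_snps}")
    return [
        (s, s + window_size) for s in range(0, n_snps - window_size + 1, window_size)
    ]


def impute_missing_mean(gm: GenotypeMatrix) -> np.ndarray:
    """Real-valued copy of the dosage matrix with missing entries replaced by
    the SNP's mean dosage over non-missing calls (mean-preserving)."""
    x = gm.dosages.astype(float)
    miss = gm.missing_mask()
    n_called = (~miss).sum(axis=0)
    if (n_called == 0).any():
        j = int(np.argmax(n_called == 0))
        raise GenotypeError(f"SNP {gm.snps[j].snp_id}: all calls missing, cannot impute")
    x_masked = np.where(miss, 0.0, x)
    means = x_masked.sum(axis=0) / n_called
    return np.where(miss, means[None, :], x)
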