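"""Read per-sample read counts into site pileups.

Two entry points feed the caller:

* :func:`parse_mpileup` — the plain-text output of ``samtools mpileup``
  (optionally with the ``-s`` mapping-quality column), with base-quality
  and mapping-quality filtering applied during parsing;
* :func:`read_counts_table` — a flat TSV of per-sample strand-split
  counts, the format the simulator emits.

Both produce :class:`SitePileup` objects: for one candidate alteration
(position + base change / indel), the filtered depth ``DP`` and supporting
read count ``AO`` of every sample in the cohort, split by strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "AlterationKey",
    "SampleCounts",
    "SitePileup",
    "PileupParseError",
    "CountsValidationError",
    "parse_mpileup",
    "read_counts_table",
    "write_counts_table",
    "DEFAULT_MIN_BQ",
    "DEFAULT_MIN_MQ",
]

DEFAULT_MIN_BQ = 13
DEFAULT_MIN_MQ = 20

_SNV_BASES = "ACGT"


class PileupParseError(ValueError):
    """Malformed mpileup input (message names the offending line)."""


class CountsValidationError(ValueError):
    """Counts-table rows violating the count invariants."""


@dataclass(frozen=True, order=True)
class AlterationKey:
    """A candidate alteration: VCF-style left-anchored, 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if len(self.ref) == len(self.alt) == 1:
            if self.ref == self.alt:
                raise ValueError("SNV requires ref != alt")
        elif len(self.alt) > len(self.ref):
            if not self.alt.startswith(self.ref):
                raise ValueError(f"insertion alt {self.alt!r} must extend ref {self.ref!r}")
        elif len(self.ref) > len(self.alt):
            if not self.ref.startswith(self.alt):
                raise ValueError(f"deletion ref {self.ref!r} must extend alt {self.alt!r}")
        else:
            raise ValueError(f"unsupported alteration {self.ref!r}>{self.alt!r}")

    @property
    def alt_class(self) -> str:
        """One of ``SNV``, ``INS``, ``DEL``."""
        if len(self.ref) == len(self.alt):
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def base_change(self) -> str | None:
        """``"G>T"``-style label for SNVs, None for indels."""
        if self.alt_class != "SNV":
            return None
        return f"{self.ref}>{self.alt}"


@dataclass
class SampleCounts:
    """Strand-split filtered depth and alternate counts for one sample."""

    sample_id: str
    dp_fwd: int = 0
    dp_rev: int = 0
    ao_fwd: int = 0
    ao_rev: int = 0

    def __post_init__(self) -> None:
        if min(self.dp_fwd, self.dp_rev, self.ao_fwd, self.ao_rev) < 0:
            raise CountsValidationError(f"negative count for sample {self.sample_id}")
        if self.ao_fwd > self.dp_fwd or self.ao_rev > self.dp_rev:
            raise CountsValidationError(
                f"AO exceeds DP on a strand for sample {self.sample_id}: "
                f"AO=({self.ao_fwd},{self.ao_rev}) DP=({self.dp_fwd},{self.dp_rev})"
            )

    @property
    def dp(self) -> int:
        return self.dp_fwd + self.dp_rev

    @property
    def ao(self) -> int:
        return self.ao_fwd + self.ao_rev

    @property
    def ro(self) -> int:
        return self.dp - self.ao

    @property
    def vaf(self) -> float | None:
        return self.ao / self.dp if self.dp > 0 else None


@dataclass
class SitePileup:
    """All samples' counts for one candidate alteration."""

    key: AlterationKey
    samples: list[SampleCounts] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CountsValidationError(f"duplicate sample ids in pileup at {self.key}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


# ---------------------------------------------------------------------------
# mpileup parsing


def _parse_indel_token(bases: str, i: int, lineno: int) -> tuple[str, bool, int]:
    """Parse ``+nSEQ``/``-nSEQ`` starting at ``bases[i]``.

    Returns (sequence uppercased, is_insertion, index after the token).
    """
    is_ins = bases[i] == "+"
    j = i + 1
    while j < len(bases) and bases[j].isdigit():
        j += 1
    if j == i + 1:
        raise PileupParseError(f"line {lineno}: indel token without length at column offset {i}")
    n = int(bases[i + 1 : j])
    seq = bases[j : j + n]
    if len(seq) < n:
        raise PileupParseError(f"line {lineno}: indel sequence shorter than declared length {n}")
    return seq.upper(), is_ins, j + n


def _parse_base_column(
    ref: str,
    bases: str,
    quals: str,
    mquals: str | None,
    min_bq: int,
    min_mq: int | None,
    lineno: int,
) -> tuple[int, int, dict[tuple[str, str], tuple[int, int]]]:
    """Parse one sample's base-call string.

    Returns (dp_fwd, dp_rev, {(kind, payload): (ao_fwd, ao_rev)}) where
    kind is one of ``snv``/``ins``/``del`` and payload the alt base or
    the inserted/deleted sequence.  A read contributes only when its base
    quality (and mapping quality, when available) passes the thresholds.
    """
    ref = ref.upper()
    dp_fwd = dp_rev = 0
    alts: dict[tuple[str, str], list[int]] = {}
    i = 0  # position in base string
    qi = 0  # position in quality string(s)
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"line {lineno}: dangling '^' in base string")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            # An indel not attached to a preceding base symbol is malformed.
            raise PileupParseError(f"line {lineno}: orphan indel token at column offset {i}")

        # every remaining symbol consumes one BQ (and MQ) character
        if qi >= len(quals):
            raise PileupParseError(f"line {lineno}: base-quality string shorter than base calls")
        bq = ord(quals[qi]) - 33
        mq_ok = True
        if mquals is not None and min_mq is not None:
            if qi >= len(mquals):
                raise PileupParseError(f"line {lineno}: mapping-quality string shorter than base calls")
            mq_ok = (ord(mquals[qi]) - 33) >= min_mq
        qi += 1
        passing = bq >= min_bq and mq_ok

        i += 1
        indel: tuple[str, bool] | None = None
        if i < n and bases[i] in "+-":
            seq, is_ins, i = _parse_indel_token(bases, i, lineno)
            indel = (seq, is_ins)

        if c in ".,":
            forward = c == "."
            allele: tuple[str, str] | None = None
        elif c.upper() in _SNV_BASES:
            forward = c.isupper()
            allele = ("snv", c.upper())
        elif c in "Nn":
            # ambiguous call: passes through depth but supports nothing
            forward = c == "N"
            allele = None
        elif c == "*":
            # deletion-spanning placeholder: depth only (strand unknown,
            # attributed to forward)
            forward = True
            allele = None
        elif c in "><":
            # reference skip: consumes a quality char, contributes nothing
            continue
        else:
            raise PileupParseError(f"line {lineno}: unknown character {c!r} in base string")

        if not passing:
            continue
        if forward:
            dp_fwd += 1
        else:
            dp_rev += 1
        if allele is not None:
            alts.setdefault(allele, [0, 0])[0 if forward else 1] += 1
        if indel is not None:
            seq, is_ins = indel
            # strand of the indel follows the case of its sequence as printed
            printed = bases[i - len(seq) : i]
            fwd_indel = printed == printed.upper()
            key = ("ins" if is_ins else "del", seq)
            alts.setdefault(key, [0, 0])[0 if fwd_indel else 1] += 1

    if qi != len(quals):
        raise PileupParseError(
            f"line {lineno}: base-quality string length mismatch ({len(quals)} quals, {qi} base calls)"
        )
    return dp_fwd, dp_rev, {k: (v[0], v[1]) for k, v in alts.items()}


def parse_mpileup(
    stream: Iterable[str],
    sample_ids: Sequence[str],
    min_bq: int = DEFAULT_MIN_BQ,
    min_mq: int | None = DEFAULT_MIN_MQ,
) -> Iterator[SitePileup]:
    """Parse samtools-mpileup text into per-alteration pileups.

    Supports the plain 3-column-per-sample form and the ``-s`` form with a
    fourth mapping-quality column; in the plain form ``min_mq`` cannot be
    applied and is ignored.  One :class:`SitePileup` is yielded per
    (position, observed alteration); depth is shared across alterations at
    a position.
    """
    n_samp = len(sample_ids)
    if n_samp < 1:
        raise ValueError("need at least one sample id")
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 3 + 4 * n_samp:
            has_mq = True
        elif len(fields) == 3 + 3 * n_samp:
            has_mq = False
        else:
            raise PileupParseError(
                f"line {lineno}: expected {3 + 3 * n_samp} or {3 + 4 * n_samp} columns "
                f"for {n_samp} samples, got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: bad position {pos_s!r}") from exc

        per_sample: list[tuple[int, int, dict]] = []
        width = 4 if has_mq else 3
        for s in range(n_samp):
            base_idx = 3 + width * s
            try:
                depth = int(fields[base_idx])
            except ValueError as exc:
                raise PileupParseError(f"line {lineno}: bad depth field") from exc
            bases = fields[base_idx + 1] if depth > 0 else ""
            quals = fields[base_idx + 2] if depth > 0 else ""
            mquals = fields[base_idx + 3] if (has_mq and depth > 0) else None
            per_sample.append(
                _parse_base_column(ref, bases, quals, mquals, min_bq, min_mq, lineno)
            )

        observed: dict[tuple[str, str], None] = {}
        for _, _, alts in per_sample:
            for allele in alts:
                observed.setdefault(allele, None)
        for kind, payload in observed:
            if kind == "snv":
                key = AlterationKey(chrom, pos, ref, payload)
            elif kind == "ins":
                key = AlterationKey(chrom, pos, ref, ref + payload)
            else:
                key = AlterationKey(chrom, pos, ref + payload, ref)
            counts = []
            for sid, (dpf, dpr, alts) in zip(sample_ids, per_sample):
                aof, aor = alts.get((kind, payload), (0, 0))
                counts.append(SampleCounts(sid, dpf, dpr, aof, aor))
            yield SitePileup(key, counts)


# ---------------------------------------------------------------------------
# counts table

_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "DP_fwd", "DP_rev", "AO_fwd", "AO_rev"]


def write_counts_table(pileups: Iterable[SitePileup], path_or_fh) -> None:
    """Write pileups as the flat strand-split TSV (one row per sample)."""
    own = isinstance(path_or_fh, (str, bytes))
    fh: IO[str] = open(path_or_fh, "w") if own else path_or_fh
    try:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for p in pileups:
            k = p.key
            for s in p.samples:
                fh.write(
                    f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{s.sample_id}\t"
                    f"{s.dp_fwd}\t{s.dp_rev}\t{s.ao_fwd}\t{s.ao_rev}\n"
                )
    finally:
        if own:
            fh.close()


def read_counts_table(path_or_fh) -> list[SitePileup]:
    """Read the strand-split counts TSV back into pileups.

    Sample order is the order of first encounter in the file; a sample
    missing a row for some alteration gets AO=0 with DP copied from a
    sibling alteration at the same position.
    """
    own = isinstance(path_or_fh, (str, bytes))
    fh = open(path_or_fh) if own else path_or_fh
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _TABLE_COLUMNS:
            raise CountsValidationError(
                f"bad header: expected {_TABLE_COLUMNS}, got {header}"
            )
        sample_order: dict[str, None] = {}
        rows: dict[AlterationKey, dict[str, SampleCounts]] = {}
        key_order: list[AlterationKey] = []
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_TABLE_COLUMNS):
                raise CountsValidationError(f"row {rowno}: expected {len(_TABLE_COLUMNS)} columns")
            chrom, pos_s, ref, alt, sample = row[:5]
            try:
                pos = int(pos_s)
                dpf, dpr, aof, aor = (int(x) for x in row[5:])
            except ValueError as exc:
                raise CountsValidationError(f"row {rowno}: non-integer count") from exc
            try:
                key = AlterationKey(chrom, pos, ref, alt)
                counts = SampleCounts(sample, dpf, dpr, aof, aor)
            except (ValueError, CountsValidationError) as exc:
                raise CountsValidationError(f"row {rowno}: {exc}") from exc
            if key not in rows:
                rows[key] = {}
                key_order.append(key)
            if sample in rows[key]:
                raise CountsValidationError(f"row {rowno}: duplicate entry for {key} / {sample}")
            rows[key][sample] = counts
            sample_order.setdefault(sample, None)

        samples = list(sample_order)
        # depth fallback for samples missing at an alteration: any sibling
        # alteration at the same (chrom, pos)
        by_pos: dict[tuple[str, int], dict[str, SampleCounts]] = {}
        for key in key_order:
            by_pos.setdefault((key.chrom, key.pos), {}).update(rows[key])

        out = []
        for key in key_order:
            counts_list = []
            for sid in samples:
                c = rows[key].get(sid)
                if c is None:
                    sib = by_pos[(key.chrom, key.pos)].get(sid)
                    if sib is not None:
                        c = SampleCounts(sid, sib.dp_fwd, sib.dp_rev, 0, 0)
                    else:
                        c = SampleCounts(sid)
                counts_list.append(c)
            out.append(SitePileup(key, counts_list))
        return out
    finally:
        if own:
            fh.close()
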