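"""Reference sequence and variant I/O.

Transcript models (exon/intron structure on a genome), HGVS-c and VCF variant
parsing, bidirectional c./genomic coordinate maps, and classification of each
variant into a splicing-relevant region (consensus splice site, polypyrimidine
tract, branch-point window, exonic ESR space, near- or deep-intronic).

Internal coordinates are 0-based half-open genomic; HGVS and VCF surfaces are
1-based.  The deep-intronic boundary is strictly more than 150 nt from the
nearest exon.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Region labels, in a fixed order used for integer encoding in feature vectors.
REGIONS = (
    "exonic_consensus",
    "intronic_consensus_5ss",
    "intronic_consensus_3ss",
    "ppt",
    "bp_region",
    "exonic_esr",
    "near_intronic",
    "deep_intronic",
)
REGION_CODE = {name: i for i, name in enumerate(REGIONS)}

DEEP_INTRONIC_CUTOFF = 150  # nt; strictly greater than this from nearest exon
DONOR_INTRON_CONSENSUS = 6  # intron +1..+6
ACCEPTOR_INTRON_CONSENSUS = 4  # intron -1..-4 (the -5..-20 stretch is PPT/BP)
EXON_CONSENSUS = 3  # exonic bases adjacent to each splice site
PPT_WINDOW = (5, 17)  # intron -5..-17 from the acceptor
BP_WINDOW = (18, 44)  # intron -18..-44 from the acceptor
DEFAULT_FLANK = 40_000


class UnknownTranscriptError(LookupError):
    pass


class CoordinateRangeError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    """The stated reference allele disagrees with the genome (reported, not fixed)."""


class NullVariantError(ValueError):
    """ref == alt: not a variant."""


class HgvsSyntaxError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class Genome:
    """Uppercase sequence access over a dict of contigs or a FASTA file."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {k: v.upper() for k, v in contigs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contig_length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, clipped at contig edges."""
        seq = self._contigs[chrom]
        return seq[max(0, start) : max(0, end)]

    def contigs(self) -> list[str]:
        return list(self._contigs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Transcript:
    """An exon/intron structure on a genome, strand-aware.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order regardless of strand.  ``cds_start``/``cds_end`` (genomic, 0-based
    half-open over the CDS span) anchor c.1; when absent, c.1 is the first
    transcribed base.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e}) in {self.id}")
            if prev_end is not None:
                if s < prev_end:
                    raise ValueError(f"exons overlap or unsorted in {self.id}")
                if s - prev_end < 4:
                    raise ValueError(f"intron shorter than 4 nt in {self.id}")
            prev_end = e

    # -- basic geometry ----------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(self.n_introns)
        ]

    def donor_sites(self) -> list[int]:
        """Genomic position of the first intronic base (+1) of each donor."""
        if self.strand == "+":
            return [self.exons[i][1] for i in range(self.n_introns)]
        return [self.exons[i + 1][0] - 1 for i in range(self.n_introns)]

    def acceptor_sites(self) -> list[int]:
        """Genomic position of the last intronic base (-1) of each acceptor."""
        if self.strand == "+":
            return [self.exons[i + 1][0] - 1 for i in range(self.n_introns)]
        return [self.exons[i][1] for i in range(self.n_introns)]

    # -- spliced (transcription-order) indexing ----------------------------
    def _tx_exons(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))

    def spliced_index(self, g: int) -> int:
        """0-based index along the spliced transcript of an exonic position."""
        n = 0
        for s, e in self._tx_exons():
            if s <= g < e:
                return n + (g - s if self.strand == "+" else e - 1 - g)
            n += e - s
        raise CoordinateRangeError(f"{g} is not exonic in {self.id}")

    def g_of_spliced_index(self, n: int) -> int:
        if n < 0 or n >= self.tx_length:
            raise CoordinateRangeError(f"spliced index {n} out of range for {self.id}")
        for s, e in self._tx_exons():
            w = e - s
            if n < w:
                return s + n if self.strand == "+" else e - 1 - n
            n -= w
        raise AssertionError("unreachable")

    def is_exonic(self, g: int) -> bool:
        return any(s <= g < e for s, e in self.exons)

    def _cds_anchor_index(self) -> int:
        if self.cds_start is None:
            return 0
        g = self.cds_start if self.strand == "+" else self.cds_end - 1
        return self.spliced_index(g)


@dataclass(frozen=True)
class CPos:
    """An HGVS-c position: integer anchor plus intronic/flank offset."""

    anchor: int  # c. coordinate of the anchored exonic base (never 0)
    offset: int = 0  # 0 exonic; >0 after a donor; <0 before an acceptor

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.anchor)
        sign = "+" if self.offset > 0 else "-"
        return f"{self.anchor}{sign}{abs(self.offset)}"


def _c_of_index(t: Transcript, n: int) -> int:
    a = t._cds_anchor_index()
    return n - a + 1 if n >= a else n - a


def _index_of_c(t: Transcript, c: int) -> int:
    if c == 0:
        raise CoordinateRangeError("c.0 does not exist")
    a = t._cds_anchor_index()
    return c - 1 + a if c > 0 else c + a


def map_g_to_c(t: Transcript, g: int, flank: int = DEFAULT_FLANK) -> CPos:
    """Map a 0-based genomic position to its HGVS-c position on ``t``."""
    if t.is_exonic(g):
        return CPos(_c_of_index(t, t.spliced_index(g)))
    lo, hi = t.span
    d = +1 if t.strand == "+" else -1
    # upstream / downstream flank (no splice site at transcript ends)
    first_g = t.g_of_spliced_index(0)
    last_g = t.g_of_spliced_index(t.tx_length - 1)
    if t.strand == "+":
        upstream, downstream = g < lo, g >= hi
    else:
        upstream, downstream = g >= hi, g < lo
    if upstream or downstream:
        if upstream:
            off = -(first_g - g) * d
            anchor = _c_of_index(t, 0)
        else:
            off = (g - last_g) * d
            anchor = _c_of_index(t, t.tx_length - 1)
        if abs(off) > flank:
            raise CoordinateRangeError(f"{g} beyond {flank} nt flank of {t.id}")
        return CPos(anchor, off)
    # intronic
    for i, (istart, iend) in enumerate(t.introns()):
        if istart <= g < iend:
            if t.strand == "+":
                d_donor = g - istart + 1
                d_acc = iend - g
                donor_anchor_g, acc_anchor_g = istart - 1, iend
            else:
                d_donor = iend - g
                d_acc = g - istart + 1
                donor_anchor_g, acc_anchor_g = iend, istart - 1
            if d_donor <= d_acc:
                return CPos(_c_of_index(t, t.spliced_index(donor_anchor_g)), d_donor)
            return CPos(_c_of_index(t, t.spliced_index(acc_anchor_g)), -d_acc)
    raise CoordinateRangeError(f"{g} not mappable on {t.id}")


def map_c_to_g(t: Transcript, c: CPos | str, flank: int = DEFAULT_FLANK) -> int:
    """Map an HGVS-c position to its 0-based genomic position on ``t``."""
    if isinstance(c, str):
        c = parse_c_position(c)
    g_anchor = t.g_of_spliced_index(_index_of_c(t, c.anchor))
    if c.offset == 0:
        return g_anchor
    d = +1 if t.strand == "+" else -1
    g = g_anchor + d * c.offset
    lo, hi = t.span
    if g < lo - flank or g >= hi + flank:
        raise CoordinateRangeError(f"{c} beyond {flank} nt flank of {t.id}")
    return g


_C_POS_RE = re.compile(r"^(-?\d+)(?:([+-])(\d+))?$")


def parse_c_position(text: str) -> CPos:
    m = _C_POS_RE.match(text)
    if not m:
        raise HgvsSyntaxError(f"bad c. position {text!r}")
    anchor = int(m.group(1))
    if anchor == 0:
        raise HgvsSyntaxError("c.0 does not exist")
    off = int(m.group(3)) if m.group(2) else 0
    if m.group(2) == "-":
        off = -off
    return CPos(anchor, off)


@dataclass(frozen=True)
class GenomicVariant:
    """A normalized small variant: 1-based ``pos`` of the first reference base.

    After :func:`normalize`, ``ref`` and ``alt`` share no common prefix or
    suffix and indels are left-aligned; a pure insertion has ``ref == ""`` and
    is placed *before* ``pos``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    @property
    def start(self) -> int:
        """0-based start of the affected reference interval."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based end (half-open) of the affected reference interval."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def normalize(variant: GenomicVariant, genome: Genome) -> GenomicVariant:
    """Trim to minimal representation and left-align indels against ``genome``."""
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    obs = genome.fetch(variant.chrom, pos - 1, pos - 1 + len(ref))
    if ref and obs != ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{pos} expected {ref!r}, genome has {obs!r}"
        )
    # trim common suffix, then prefix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise NullVariantError(f"{variant.chrom}:{variant.pos} ref == alt")
    # left-align pure indels by rotation
    if not ref or not alt:
        moving = alt if not ref else ref
        while pos > 1:
            prev = genome.fetch(variant.chrom, pos - 2, pos - 1)
            if prev and moving and prev == moving[-1]:
                moving = prev + moving[:-1]
                pos -= 1
                if ref:
                    # deletion window shifts with its content
                    obs = genome.fetch(variant.chrom, pos - 1, pos - 1 + len(moving))
                    if obs != moving:
                        pos += 1
                        moving = moving[1:] + moving[0]
                        break
            else:
                break
        if ref:
            ref = moving
        else:
            alt = moving
    return replace(variant, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# HGVS parsing / formatting
# ---------------------------------------------------------------------------

_HGVS_RE = re.compile(
    r"^(?P<tx>[A-Za-z0-9_.]+):c\.(?P<body>.+)$"
)
_SUB_RE = re.compile(r"^(?P<pos>[\d+-]+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_RANGE_RE = re.compile(
    r"^(?P<p1>-?\d+(?:[+-]\d+)?)(?:_(?P<p2>-?\d+(?:[+-]\d+)?))?"
    r"(?P<op>del|dup|ins|delins)(?P<seq>[ACGT]*)$"
)


class TranscriptIndex:
    """Lookup of :class:`Transcript` by accession."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self._by_id = {t.id: t for t in transcripts}

    def __getitem__(self, tx_id: str) -> Transcript:
        try:
            return self._by_id[tx_id]
        except KeyError:
            raise UnknownTranscriptError(tx_id) from None

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self._by_id

    @classmethod
    def from_exon_table(cls, path) -> "TranscriptIndex":
        """TSV with columns transcript, chrom, strand, exon_start, exon_end,
        cds_start, cds_end (one row per exon; 0-based half-open)."""
        df = pd.read_csv(path, sep="\t")
        out = []
        for tx_id, grp in df.groupby("transcript", sort=False):
            exons = tuple(
                sorted(zip(grp["exon_start"].astype(int), grp["exon_end"].astype(int)))
            )
            row = grp.iloc[0]
            cds_s = int(row["cds_start"]) if pd.notna(row.get("cds_start")) else None
            cds_e = int(row["cds_end"]) if pd.notna(row.get("cds_end")) else None
            out.append(
                Transcript(
                    id=str(tx_id),
                    chrom=str(row["chrom"]),
                    strand=str(row["strand"]),
                    exons=exons,
                    cds_start=cds_s,
                    cds_end=cds_e,
                )
            )
        return cls(out)

    def to_exon_table(self, path) -> None:
        rows = []
        for t in self:
            for s, e in t.exons:
                rows.append(
                    dict(
                        transcript=t.id,
                        chrom=t.chrom,
                        strand=t.strand,
                        exon_start=s,
                        exon_end=e,
                        cds_start=t.cds_start if t.cds_start is not None else "",
                        cds_end=t.cds_end if t.cds_end is not None else "",
                    )
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_gff3(cls, path) -> "TranscriptIndex":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        out = []
        for feat in db.features_of_type(("mRNA", "transcript")):
            exons = tuple(
                sorted(
                    (e.start - 1, e.end)
                    for e in db.children(feat, featuretype="exon")
                )
            )
            if exons:
                out.append(
                    Transcript(
                        id=feat.id,
                        chrom=feat.seqid,
                        strand=feat.strand,
                        exons=exons,
                    )
                )
        return cls(out)


def _c_range_to_g(t: Transcript, p1: CPos, p2: CPos, flank: int) -> tuple[int, int]:
    g1 = map_c_to_g(t, p1, flank)
    g2 = map_c_to_g(t, p2, flank)
    lo, hi = min(g1, g2), max(g1, g2)
    return lo, hi + 1


def parse_hgvs(
    text: str,
    transcripts: TranscriptIndex,
    genome: Genome,
    flank: int = DEFAULT_FLANK,
) -> tuple[Transcript, GenomicVariant, str]:
    """Parse ``<transcript>:c.<change>`` into a normalized genomic variant.

    Substitutions, del, dup, ins and delins are supported.  Alleles are given
    in transcript orientation and are reverse-complemented onto the genome for
    minus-strand transcripts.  The stated reference allele is checked against
    the genome; a mismatch raises :class:`ReferenceMismatchError`.
    """
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise HgvsSyntaxError(f"not an HGVS c. description: {text!r}")
    t = transcripts[m.group("tx")]
    body = m.group("body")

    sub = _SUB_RE.match(body)
    if sub:
        cpos = parse_c_position(sub.group("pos"))
        ref_t, alt_t = sub.group("ref"), sub.group("alt")
        if ref_t == alt_t:
            raise NullVariantError(f"{text}: ref == alt")
        g = map_c_to_g(t, cpos, flank)
        ref_g = ref_t if t.strand == "+" else revcomp(ref_t)
        alt_g = alt_t if t.strand == "+" else revcomp(alt_t)
        var = GenomicVariant(t.chrom, g + 1, ref_g, alt_g, id=text)
        var = normalize(var, genome)
        return t, var, f"c.{cpos}{ref_t}>{alt_t}"

    rng = _RANGE_RE.match(body)
    if not rng:
        raise HgvsSyntaxError(f"unsupported HGVS change: {body!r}")
    p1 = parse_c_position(rng.group("p1"))
    p2 = parse_c_position(rng.group("p2")) if rng.group("p2") else p1
    op, seq = rng.group("op"), rng.group("seq")
    lo, hi = _c_range_to_g(t, p1, p2, flank)
    ref_seq = genome.fetch(t.chrom, lo, hi)
    if op == "del":
        if seq:
            stated = seq if t.strand == "+" else revcomp(seq)
            if stated != ref_seq:
                raise ReferenceMismatchError(f"{text}: deleted bases mismatch genome")
        var = GenomicVariant(t.chrom, lo + 1, ref_seq, "", id=text)
    elif op == "dup":
        var = GenomicVariant(t.chrom, hi + 1, "", ref_seq, id=text)
    elif op == "ins":
        if not seq:
            raise HgvsSyntaxError(f"{text}: ins requires a sequence")
        if hi - lo != 2:
            raise HgvsSyntaxError(f"{text}: ins anchors must be adjacent")
        ins_g = seq if t.strand == "+" else revcomp(seq)
        var = GenomicVariant(t.chrom, lo + 2, "", ins_g, id=text)
    else:  # delins
        if not seq:
            raise HgvsSyntaxError(f"{text}: delins requires a sequence")
        alt_g = seq if t.strand == "+" else revcomp(seq)
        var = GenomicVariant(t.chrom, lo + 1, ref_seq, alt_g, id=text)
    var = normalize(var, genome)
    canon = f"c.{p1}" + (f"_{p2}" if rng.group("p2") else "") + op + seq
    return t, var, canon


def format_hgvs(t: Transcript, var: GenomicVariant, flank: int = DEFAULT_FLANK) -> str:
    """Render a normalized genomic variant as ``<tx>:c.<change>``."""
    if var.is_snv:
        cpos = map_g_to_c(t, var.start, flank)
        ref = var.ref if t.strand == "+" else revcomp(var.ref)
        alt = var.alt if t.strand == "+" else revcomp(var.alt)
        return f"{t.id}:c.{cpos}{ref}>{alt}"
    if not var.alt:  # deletion
        g_lo, g_hi = var.start, var.end - 1
        if t.strand == "-":
            g_lo, g_hi = g_hi, g_lo
        c1, c2 = map_g_to_c(t, g_lo, flank), map_g_to_c(t, g_hi, flank)
        body = f"{c1}del" if var.start == var.end - 1 else f"{c1}_{c2}del"
        return f"{t.id}:c.{body}"
    if not var.ref:  # insertion before var.start
        g_before, g_at = var.start - 1, var.start
        if t.strand == "-":
            g_before, g_at = g_at, g_before
        c1, c2 = map_g_to_c(t, g_before, flank), map_g_to_c(t, g_at, flank)
        ins = var.alt if t.strand == "+" else revcomp(var.alt)
        return f"{t.id}:c.{c1}_{c2}ins{ins}"
    g_lo, g_hi = var.start, var.end - 1
    if t.strand == "-":
        g_lo, g_hi = g_hi, g_lo
    c1, c2 = map_g_to_c(t, g_lo, flank), map_g_to_c(t, g_hi, flank)
    alt = var.alt if t.strand == "+" else revcomp(var.alt)
    body = f"{c1}delins{alt}" if c1 == c2 else f"{c1}_{c2}delins{alt}"
    return f"{t.id}:c.{body}"


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> Iterator[GenomicVariant]:
    """Stream one :class:`GenomicVariant` per ALT allele of a VCF v4.0+ file.

    Symbolic and breakend ALT alleles carry no sequence and are skipped with a
    warning; malformed records are reported with their line context and the
    stream continues.
    """
    from cyvcf2 import VCF

    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if not alt or not re.fullmatch(r"[ACGTNacgtn]+", alt):
                warnings.warn(
                    f"skipping non-sequence ALT {alt!r} at {rec.CHROM}:{rec.POS}"
                )
                continue
            yield GenomicVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF.upper(),
                alt=alt.upper(),
                id=rec.ID,
            )


def write_vcf(variants: Iterable[GenomicVariant], path, contigs=None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs or []:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


@dataclass
class VariantContext:
    """A variant joined with its transcript, region label and distances."""

    variant: GenomicVariant
    transcript: Transcript
    c_notation: str
    region: str
    nearest_site_kind: str  # donor | acceptor
    nearest_site_pos: int  # genomic position of the +1/-1 intronic base
    dist_to_nearest_site: int  # signed; see classify_position
    exon_size: int
    intron_size: int
    rel_pos: float

    @property
    def region_code(self) -> int:
        return REGION_CODE[self.region]


def _feature_of(t: Transcript, g: int) -> tuple[str, int]:
    """('exon'|'intron'|'flank', index) containing genomic position g."""
    for i, (s, e) in enumerate(t.exons):
        if s <= g < e:
            return "exon", i
    for i, (s, e) in enumerate(t.introns()):
        if s <= g < e:
            return "intron", i
    return "flank", -1


def classify_position(t: Transcript, g: int) -> dict:
    """Region label and distances for a single genomic position.

    Signed distance convention: intronic positions are +d after a donor and
    -d before an acceptor (HGVS-like); exonic positions are -d when the
    nearest site is the downstream donor (d=1 at the last exonic base) and
    +d when it is the upstream acceptor (d=1 at the first exonic base).
    """
    kind, idx = _feature_of(t, g)
    d = +1 if t.strand == "+" else -1
    if kind == "exon":
        s, e = t.exons[idx]
        exon_len = e - s
        # transcription-order offsets within the exon (1-based from each end)
        n_in = t.spliced_index(g)
        first_in = t.spliced_index(s if t.strand == "+" else e - 1)
        off_from_start = n_in - first_in + 1
        off_from_end = exon_len - off_from_start + 1
        tx_idx = idx if t.strand == "+" else len(t.exons) - 1 - idx
        has_acceptor = tx_idx > 0
        has_donor = tx_idx < len(t.exons) - 1
        choices = []
        if has_donor:
            donor_g = t.donor_sites()[idx if t.strand == "+" else idx - 1]
            choices.append(("donor", donor_g, off_from_end))
        if has_acceptor:
            acc_g = t.acceptor_sites()[idx - 1 if t.strand == "+" else idx]
            choices.append(("acceptor", acc_g, off_from_start))
        kind_, site_g, dd = min(choices, key=lambda x: x[2]) if choices else (
            "donor",
            t.exons[idx][1] if t.strand == "+" else t.exons[idx][0] - 1,
            off_from_end,
        )
        region = "exonic_consensus" if (choices and dd <= EXON_CONSENSUS) else "exonic_esr"
        signed = -dd if kind_ == "donor" else +dd
        return dict(
            region=region,
            nearest_site_kind=kind_,
            nearest_site_pos=site_g,
            dist=signed,
            exon_size=exon_len,
            intron_size=0,
            rel_pos=(off_from_start - 1) / max(1, exon_len - 1) if exon_len > 1 else 0.0,
        )
    if kind == "intron":
        s, e = t.introns()[idx]
        intron_len = e - s
        if t.strand == "+":
            d_donor, d_acc = g - s + 1, e - g
            donor_g, acc_g = s, e - 1
        else:
            d_donor, d_acc = e - g, g - s + 1
            donor_g, acc_g = e - 1, s
        if d_donor <= d_acc:
            side, site_g, dd, signed = "donor", donor_g, d_donor, +d_donor
        else:
            side, site_g, dd, signed = "acceptor", acc_g, d_acc, -d_acc
        if dd > DEEP_INTRONIC_CUTOFF:
            region = "deep_intronic"
        elif side == "donor":
            region = (
                "intronic_consensus_5ss" if dd <= DONOR_INTRON_CONSENSUS else "near_intronic"
            )
        else:
            if dd <= ACCEPTOR_INTRON_CONSENSUS:
                region = "intronic_consensus_3ss"
            elif PPT_WINDOW[0] <= dd <= PPT_WINDOW[1]:
                region = "ppt"
            elif BP_WINDOW[0] <= dd <= BP_WINDOW[1]:
                region = "bp_region"
            else:
                region = "near_intronic"
        rel = (d_donor - 1) / max(1, intron_len - 1)
        return dict(
            region=region,
            nearest_site_kind=side,
            nearest_site_pos=site_g,
            dist=signed,
            exon_size=0,
            intron_size=intron_len,
            rel_pos=rel,
        )
    # flank: nearest boundary is a transcript end, not a splice site; label by
    # distance like an intron but anchored on the terminal exon boundary.
    first_g = t.g_of_spliced_index(0)
    last_g = t.g_of_spliced_index(t.tx_length - 1)
    d_first, d_last = abs(g - first_g), abs(g - last_g)
    lo, hi = t.span
    if d_first <= d_last:
        side, site_g, dd = "acceptor", first_g, d_first
        signed = -dd
    else:
        side, site_g, dd = "donor", last_g, d_last
        signed = +dd
    region = "deep_intronic" if dd > DEEP_INTRONIC_CUTOFF else "near_intronic"
    return dict(
        region=region,
        nearest_site_kind=side,
        nearest_site_pos=site_g,
        dist=signed,
        exon_size=0,
        intron_size=0,
        rel_pos=0.0,
    )


def classify_region(
    t: Transcript,
    variant: GenomicVariant,
    flank: int = DEFAULT_FLANK,
) -> VariantContext:
    """Classify a variant into exactly one region of its transcript.

    Multi-nucleotide variants are anchored at their most splice-proximal
    affected base (ties broken toward the donor side).
    """
    lo, hi = t.span
    if variant.end <= lo - flank or variant.start >= hi + flank:
        raise CoordinateRangeError(
            f"{variant.chrom}:{variant.pos} outside {t.id} ± {flank} nt"
        )
    positions = range(variant.start, max(variant.start + 1, variant.end))
    infos = [classify_position(t, g) for g in positions]

    def proximity(info):
        # smaller |dist| wins; donor side wins ties
        return (abs(info["dist"]), 0 if info["nearest_site_kind"] == "donor" else 1)

    best = min(infos, key=proximity)
    try:
        c_notation = format_hgvs(t, variant, flank).split(":", 1)[1]
    except CoordinateRangeError:
        c_notation = ""
    return VariantContext(
        variant=variant,
        transcript=t,
        c_notation=c_notation,
        region=best["region"],
        nearest_site_kind=best["nearest_site_kind"],
        nearest_site_pos=best["nearest_site_pos"],
        dist_to_nearest_site=best["dist"],
        exon_size=best["exon_size"],
        intron_size=best["intron_size"],
        rel_pos=best["rel_pos"],
    )
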