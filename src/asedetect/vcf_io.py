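"""Streaming VCF v4.2 reader/writer and tabular report output.

Only the fields the ASE pipeline consumes are modelled: locus, alleles,
QUAL, FILTER, a small INFO subset (FS, QD, DP) and per-sample GT/AD.
Parsing is line-based and constant-memory in the number of records, so
arbitrarily large single-chromosome VCFs stream through the filter
cascade without being materialised.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

__all__ = [
    "SampleCall",
    "VariantSite",
    "VcfError",
    "VcfFormatError",
    "VcfRecordError",
    "VcfReader",
    "read_vcf",
    "parse_sample_call",
    "write_vcf",
    "write_report",
]

_VALID_ALLELE_CHARS = frozenset("ACGTN")

# INFO keys retained; everything else is dropped at parse time.
_INFO_KEYS = ("FS", "QD", "DP")


class VcfError(ValueError):
    """Base class for VCF parsing problems."""


class VcfFormatError(VcfError):
    """The file header is malformed (e.g. missing the #CHROM line)."""


class VcfRecordError(VcfError):
    """A data line is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SampleCall:
    """One genotype call: allele indices (GT) and unfiltered allele depths (AD).

    ``gt`` is a pair of allele indices (0 = reference) or ``None`` when the
    call is missing.  ``phased`` records the original GT separator purely so
    serialisation can round-trip; no downstream logic looks at phase.
    """

    gt: tuple[int, int] | None
    ad: tuple[int, ...] | None
    missing: bool
    phased: bool = False

    @property
    def is_het_ref_alt(self) -> bool:
        """True iff the genotype is exactly the {0, 1} heterozygote."""
        return not self.missing and self.gt is not None and set(self.gt) == {0, 1}

    @property
    def is_homozygous(self) -> bool:
        return not self.missing and self.gt is not None and self.gt[0] == self.gt[1]


@dataclass
class VariantSite:
    """One VCF record with calls aligned to the header sample order."""

    chrom: str
    pos: int  # 1-based, as in VCF
    id: str | None
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    filter_status: str
    info: dict[str, float]
    calls: list[SampleCall] = field(default_factory=list)

    @property
    def is_indel(self) -> bool:
        """Any allele longer than one base marks the site as an indel."""
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_biallelic_snp(self) -> bool:
        return len(self.alts) == 1 and len(self.ref) == 1 and len(self.alts[0]) == 1

    def key(self) -> tuple[str, int, str, str]:
        """Variant identity used to join tables: (chrom, pos, ref, alts-joined)."""
        return (self.chrom, self.pos, self.ref, ",".join(self.alts))


def _check_allele(allele: str, line_number: int) -> str:
    up = allele.upper()
    if not up or not set(up) <= _VALID_ALLELE_CHARS:
        raise VcfRecordError(
            f"unsupported allele {allele!r} (symbolic/breakend alleles are rejected)",
            line_number,
        )
    return up


def parse_sample_call(gt_field: str, ad_field: str | None, n_alts: int) -> SampleCall:
    """Parse the GT and AD sub-fields of one sample column.

    ``"./."`` (or any GT containing ``.``) and an absent/``"."`` AD both
    yield a missing call.  An AD whose length disagrees with the allele
    count is surfaced as a warning and the call is treated as missing.
    """
    phased = "|" in gt_field
    sep = "|" if phased else "/"
    tokens = gt_field.split(sep)
    if gt_field in (".", "") or any(t in (".", "") for t in tokens):
        return SampleCall(gt=None, ad=None, missing=True, phased=phased)
    if len(tokens) != 2:
        raise VcfError(f"non-diploid GT field {gt_field!r}")
    try:
        gt = (int(tokens[0]), int(tokens[1]))
    except ValueError as exc:
        raise VcfError(f"unparsable GT field {gt_field!r}") from exc
    if max(gt) > n_alts or min(gt) < 0:
        raise VcfError(f"GT allele index out of range in {gt_field!r}")

    if ad_field is None or ad_field in (".", ""):
        return SampleCall(gt=gt, ad=None, missing=True, phased=phased)
    try:
        ad = tuple(int(tok) for tok in ad_field.split(","))
    except ValueError as exc:
        raise VcfError(f"non-integer AD token in {ad_field!r}") from exc
    if len(ad) != n_alts + 1:
        warnings.warn(
            f"AD length {len(ad)} disagrees with allele count {n_alts + 1}; "
            "call treated as missing",
            stacklevel=2,
        )
        return SampleCall(gt=gt, ad=None, missing=True, phased=phased)
    if any(a < 0 for a in ad):
        raise VcfError(f"negative AD value in {ad_field!r}")
    return SampleCall(gt=gt, ad=ad, missing=False, phased=phased)


def _parse_info(info_field: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if info_field in (".", ""):
        return out
    for chunk in info_field.split(";"):
        if "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        if key in _INFO_KEYS:
            try:
                out[key] = float(value)
            except ValueError:
                continue
    return out


class VcfReader:
    """Iterate ``VariantSite`` records from a VCF text stream or path.

    The header is consumed eagerly so ``samples`` is available before
    iteration; records are parsed lazily, one line at a time.
    """

    def __init__(self, source: Union[str, os.PathLike, TextIO]):
        if isinstance(source, (str, os.PathLike)):
            self._stream: TextIO = open(source, "rt")
            self._owns_stream = True
        else:
            self._stream = source
            self._owns_stream = False
        self._line_number = 0
        self.samples: list[str] = []
        self._read_header()

    def _read_header(self) -> None:
        for line in self._stream:
            self._line_number += 1
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 8:
                    raise VcfFormatError("#CHROM line has fewer than 8 columns")
                self.samples = cols[9:] if len(cols) > 9 else []
                return
            raise VcfFormatError(
                f"line {self._line_number}: expected ## header or #CHROM line"
            )
        raise VcfFormatError("no #CHROM header line found")

    def __iter__(self) -> Iterator[VariantSite]:
        n_fixed = 9 if self.samples else 8
        for line in self._stream:
            self._line_number += 1
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < n_fixed + len(self.samples):
                raise VcfRecordError(
                    f"expected {n_fixed + len(self.samples)} columns, got {len(cols)}",
                    self._line_number,
                )
            yield self._parse_record(cols)
        if self._owns_stream:
            self._stream.close()

    def _parse_record(self, cols: Sequence[str]) -> VariantSite:
        ln = self._line_number
        try:
            pos = int(cols[1])
        except ValueError as exc:
            raise VcfRecordError(f"non-integer POS {cols[1]!r}", ln) from exc
        if pos < 1:
            raise VcfRecordError(f"POS must be >= 1, got {pos}", ln)
        ref = _check_allele(cols[3], ln)
        alts = tuple(_check_allele(a, ln) for a in cols[4].split(","))
        qual = None if cols[5] == "." else float(cols[5])
        vid = None if cols[2] == "." else cols[2]
        info = _parse_info(cols[7])

        calls: list[SampleCall] = []
        if self.samples:
            fmt_keys = cols[8].split(":")
            try:
                gt_idx = fmt_keys.index("GT")
            except ValueError as exc:
                raise VcfRecordError("FORMAT lacks GT", ln) from exc
            ad_idx = fmt_keys.index("AD") if "AD" in fmt_keys else None
            for raw in cols[9:]:
                parts = raw.split(":")
                gt_field = parts[gt_idx] if gt_idx < len(parts) else "."
                ad_field = (
                    parts[ad_idx]
                    if ad_idx is not None and ad_idx < len(parts)
                    else None
                )
                try:
                    calls.append(parse_sample_call(gt_field, ad_field, len(alts)))
                except VcfError as exc:
                    raise VcfRecordError(str(exc), ln) from exc

        return VariantSite(
            chrom=cols[0],
            pos=pos,
            id=vid,
            ref=ref,
            alts=alts,
            qual=qual,
            filter_status=cols[6],
            info=info,
            calls=calls,
        )


def read_vcf(source: Union[str, os.PathLike, TextIO]) -> VcfReader:
    """Open a VCF for streaming; ``reader.samples`` holds header sample names."""
    return VcfReader(source)


def _format_call(call: SampleCall) -> str:
    sep = "|" if call.phased else "/"
    if call.gt is None:
        gt = "./."
    else:
        gt = f"{call.gt[0]}{sep}{call.gt[1]}"
    ad = "." if call.ad is None else ",".join(str(a) for a in call.ad)
    return f"{gt}:{ad}"


def write_vcf(
    sites: Iterable[VariantSite],
    samples: Sequence[str],
    dest: Union[str, os.PathLike, TextIO],
) -> None:
    """Serialise records as minimal VCF v4.2 with GT:AD genotype columns."""
    own = isinstance(dest, (str, os.PathLike))
    out: TextIO = open(dest, "wt") if own else dest  # type: ignore[arg-type]
    try:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Unfiltered allele depth">\n'
        )
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header.append("FORMAT")
            header.extend(samples)
        out.write("\t".join(header) + "\n")
        for site in sites:
            qual = "." if site.qual is None else f"{site.qual:g}"
            info = (
                ";".join(f"{k}={site.info[k]:g}" for k in _INFO_KEYS if k in site.info)
                or "."
            )
            row = [
                site.chrom,
                str(site.pos),
                site.id or ".",
                site.ref,
                ",".join(site.alts),
                qual,
                site.filter_status,
                info,
            ]
            if samples:
                row.append("GT:AD")
                row.extend(_format_call(c) for c in site.calls)
            out.write("\t".join(row) + "\n")
    finally:
        if own:
            out.close()


def _render(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if value != value:  # NaN
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_report(
    rows: Iterable[Union[Mapping, Sequence]],
    columns: Sequence[str],
    dest: Union[str, os.PathLike, TextIO],
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV report: one comment provenance line, a header, then rows.

    Rows may be mappings (selected by column name) or sequences aligned to
    ``columns``.  Floats render at 6 significant digits; ``None``/NaN as
    ``NA``.  The provenance line carries the tool version and the run's
    effective parameters; no timestamp is included so that identical runs
    produce byte-identical files.
    """
    from . import __version__

    own = isinstance(dest, (str, os.PathLike))
    out: TextIO = open(dest, "wt") if own else dest  # type: ignore[arg-type]
    try:
        prov = " ".join(f"{k}={v}" for k, v in (provenance or {}).items())
        out.write(f"# asedetect v{__version__}" + (f" {prov}" if prov else "") + "\n")
        out.write("\t".join(columns) + "\n")
        for row in rows:
            if isinstance(row, Mapping):
                values = [row.get(c) for c in columns]
            else:
                values = list(row)
                if len(values) != len(columns):
                    raise ValueError(
                        f"row has {len(values)} fields, expected {len(columns)}"
                    )
            out.write("\t".join(_render(v) for v in values) + "\n")
    finally:
        if own:
            out.close()
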