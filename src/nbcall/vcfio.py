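"""Multi-sample VCF v4.2 emission and re-ingestion.

One record per alteration with at least one variant sample.  The error
model travels in INFO (``TYPE``, ``ERR``, ``SIG``, ``NEX``), per-sample
statistics in FORMAT (``GT:QVAL:DP:RO:AO:AF:RVSB:STATUS``).  QUAL is the
maximum QVAL observed at the site.  Writing is plain deterministic text so
that write -> read -> write is a byte-level fixed point; reading goes
through pysam so external multi-sample VCFs (e.g. GATK output carrying
only DP/AO) can be re-scored.
"""

from __future__ import annotations

from typing import IO, Iterable, Sequence

import numpy as np
import pysam

from .calling import FILTER_FLAGS, SampleCall, SiteCalls
from .model import ErrorModelFit
from .pileup import AlterationKey, SampleCounts, SitePileup

__all__ = ["write_vcf", "read_vcf_calls", "VcfFormatError"]

_HIGH_VAF_GT = 0.75  # above this a called variant is written 1/1


class VcfFormatError(ValueError):
    pass


def _fmt_rate(x: float) -> str:
    return f"{x:.2e}"  # 3 significant digits, scientific


def _fmt_call(c: SampleCall) -> str:
    dp = c.counts.dp if c.counts is not None else 0
    ao = c.counts.ao if c.counts is not None else 0
    if dp == 0:
        gt = "./."
        af = "."
    else:
        vaf = ao / dp
        if c.is_variant:
            gt = "1/1" if vaf > _HIGH_VAF_GT else "0/1"
        else:
            gt = "0/0"
        af = f"{vaf:.5f}"
    rvsb = c.rvsb
    return ":".join(
        [
            gt,
            str(int(round(c.qval))),
            str(dp),
            str(dp - ao),
            str(ao),
            af,
            "." if rvsb is None else f"{rvsb:.4f}",
            c.status or ".",
        ]
    )


_HEADER_META = [
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="Alteration class (snv, ins or del)">',
    '##INFO=<ID=ERR,Number=1,Type=Float,Description="Estimated per-read error rate of the alteration across the cohort">',
    '##INFO=<ID=SIG,Number=1,Type=Float,Description="Estimated overdispersion of the error model (variance = mu + SIG*mu^2)">',
    '##INFO=<ID=NEX,Number=1,Type=Integer,Description="Samples excluded from the fit by extra-robust pre-exclusion">',
    '##FILTER=<ID=RVSB_FAIL,Description="Relative variant strand bias at or above threshold">',
    '##FILTER=<ID=PROXIMITY_FAIL,Description="Much higher-VAF called variant within the proximity window">',
    '##FILTER=<ID=LOWCONF_CHANGE_FAIL,Description="Low-confidence base change below the VAF floor">',
    '##FILTER=<ID=SAMPLE_QC_FAIL,Description="Sample exceeds the raw variant count limit">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=QVAL,Number=1,Type=Integer,Description="Phred-scaled variant quality of the sample">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">',
    '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference-supporting read count">',
    '##FORMAT=<ID=AO,Number=1,Type=Integer,Description="Alternate-supporting read count">',
    '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">',
    '##FORMAT=<ID=RVSB,Number=1,Type=Float,Description="Relative variant strand bias">',
    '##FORMAT=<ID=STATUS,Number=1,Type=String,Description="Somatic/germline status from the matched normal">',
]


def write_vcf(sites: Sequence[SiteCalls], sample_ids: Sequence[str], path_or_fh) -> None:
    """Emit sorted SiteCalls as a multi-sample VCF v4.2 text file.

    Only alterations with at least one variant sample produce a record;
    all cohort samples appear in every record.
    """
    order = [(s.key.chrom, s.key.pos, s.key.ref, s.key.alt) for s in sites]
    if order != sorted(order):
        raise VcfFormatError("write_vcf requires sites sorted by (chrom, pos, ref, alt)")

    records = [s for s in sites if s.variant_calls]
    chroms: list[str] = []
    for s in records:
        if s.key.chrom not in chroms:
            chroms.append(s.key.chrom)

    own = isinstance(path_or_fh, (str, bytes))
    fh: IO[str] = open(path_or_fh, "w") if own else path_or_fh
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nbcall\n")
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        for line in _HEADER_META:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
            + "FORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for s in records:
            by_id = {c.sample_id: c for c in s.calls}
            missing = [sid for sid in sample_ids if sid not in by_id]
            if missing:
                raise VcfFormatError(f"record {s.key} lacks samples {missing}")
            if s.record_filter is not None:
                flags = list(s.record_filter)
            else:
                flags = sorted(
                    {f for c in s.variant_calls for f in c.filter_flags},
                    key=FILTER_FLAGS.index,
                )
            filt = ";".join(flags) if flags else "PASS"
            info = (
                f"TYPE={s.key.alt_class.lower()};ERR={_fmt_rate(s.fit.e_hat)};"
                f"SIG={_fmt_rate(s.fit.sigma_hat)};NEX={s.fit.n_excluded}"
            )
            fields = [
                s.key.chrom,
                str(s.key.pos),
                ".",
                s.key.ref,
                s.key.alt,
                str(int(round(s.max_qval))),
                filt,
                info,
                "GT:QVAL:DP:RO:AO:AF:RVSB:STATUS",
            ]
            fields.extend(_fmt_call(by_id[sid]) for sid in sample_ids)
            fh.write("\t".join(fields) + "\n")
    finally:
        if own:
            fh.close()


def _classify(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "snv"
    return "ins" if len(alt) > len(ref) else "del"


def read_vcf_calls(path: str) -> list[SiteCalls]:
    """Read a multi-sample VCF back into SiteCalls.

    Requires DP and AO FORMAT fields; everything else degrades gracefully
    (no strand counts -> AO/DP attributed to the forward strand and RVSB
    undefined; no QVAL -> 0).  The result is suitable for re-scoring via
    ``SiteCalls`` -> pileup reconstruction (:func:`calls_to_pileup`).
    """
    out: list[SiteCalls] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        infos = set(vf.header.info.keys())
        fmts = set(vf.header.formats.keys())
        if "DP" not in fmts or "AO" not in fmts:
            raise VcfFormatError("VCF lacks DP/AO FORMAT fields; cannot reconstruct counts")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfFormatError(
                    f"record {rec.chrom}:{rec.pos} must carry exactly one ALT allele"
                )
            key = AlterationKey(rec.chrom, rec.pos, rec.ref, rec.alts[0])
            info = rec.info
            fit = ErrorModelFit(
                e_hat=float(info.get("ERR", 0.0)) if "ERR" in infos else 0.0,
                sigma_hat=float(info.get("SIG", 0.0)) if "SIG" in infos else 0.0,
                weights=np.ones(len(samples)),
                n_iter=0,
                converged=True,
                n_excluded=int(info.get("NEX", 0)) if "NEX" in infos else 0,
            )
            calls = []
            for sid in samples:
                sm = rec.samples[sid]
                dp = sm.get("DP")
                ao = sm.get("AO")
                if dp is None or ao is None:
                    raise VcfFormatError(
                        f"record {rec.chrom}:{rec.pos} sample {sid}: missing DP or AO"
                    )
                dp, ao = int(dp), int(ao) if not isinstance(ao, tuple) else int(ao[0])
                qv = sm.get("QVAL")
                qv = float(qv) if qv is not None else 0.0
                rvsb = sm.get("RVSB")
                status = sm.get("STATUS")
                gt = sm.get("GT")
                is_var = gt is not None and any(g not in (0, None) for g in gt)
                counts = SampleCounts(sid, dp_fwd=dp, dp_rev=0, ao_fwd=ao, ao_rev=0)
                q = 10.0 ** (-qv / 10.0)
                calls.append(
                    SampleCall(
                        sample_id=sid,
                        p_value=q,
                        q_value=q,
                        qval=qv,
                        counts=counts,
                        is_variant=is_var,
                        status=None if status in (None, ".") else str(status),
                        rvsb=None if rvsb is None else float(rvsb),
                    )
                )
            filt = tuple(rec.filter.keys())
            record_filter: tuple[str, ...] | None
            if filt == ("PASS",):
                record_filter = ()
            elif filt:
                record_filter = filt
            else:
                record_filter = None
            out.append(SiteCalls(key=key, fit=fit, calls=calls, record_filter=record_filter))
    return out


def calls_to_pileup(site: SiteCalls) -> SitePileup:
    """Reconstruct a SitePileup from re-read calls (for re-scoring)."""
    return SitePileup(site.key, [c.counts for c in site.calls if c.counts is not None])
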