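"""Minimal VCF dialect reader and writer.

The dialect is VCFv4.2, biallelic SNVs on a single chromosome, 1-based POS,
phased GT with the ``|`` separator (missing cells ``./.``), and optional
FORMAT fields GP (posterior triplet), DS (dosage), PL (phred-scaled
likelihood triplet, standard rounding), and DP (depth), plus a per-site
``IMPINFO`` INFO field.  Files written by :func:`write_vcf` round-trip
bit-identically through :func:`read_vcf` / :func:`write_vcf` (the header
carries no timestamp).  Multi-allelic or INDEL records are rejected
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VcfData", "read_vcf", "write_vcf"]

_HEADER = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior probability">',
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">',
    '##FORMAT=<ID=PL,Number=3,Type=Integer,Description="Phred-scaled genotype likelihood">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=IMPINFO,Number=1,Type=Float,Description="Imputation INFO score">',
]


@dataclass
class VcfData:
    """In-memory representation of a minimal-dialect VCF."""

    chrom: str
    positions: np.ndarray           # (M,) int64
    samples: list[str]
    gt: np.ndarray                  # (N, M, 2) int8, -1 where missing
    phased: np.ndarray              # (N, M) bool
    gp: np.ndarray | None = None    # (N, M, 3)
    ds: np.ndarray | None = None    # (N, M)
    pl: np.ndarray | None = None    # (N, M, 3) int
    dp: np.ndarray | None = None    # (N, M) int
    info: np.ndarray | None = None  # (M,) IMPINFO
    ref: np.ndarray = field(default=None)
    alt: np.ndarray = field(default=None)

    @property
    def missing(self) -> np.ndarray:
        return self.gt[..., 0] < 0


def write_vcf(
    path,
    chrom: str,
    positions: np.ndarray,
    samples: list[str],
    gt: np.ndarray,
    phased: bool | np.ndarray = True,
    missing: np.ndarray | None = None,
    gp: np.ndarray | None = None,
    ds: np.ndarray | None = None,
    pl: np.ndarray | None = None,
    dp: np.ndarray | None = None,
    info: np.ndarray | None = None,
    contig_length: int | None = None,
) -> None:
    """Write a minimal biallelic-SNV VCF (REF=A, ALT=C placeholders)."""
    positions = np.asarray(positions)
    gt = np.asarray(gt)
    N, M = gt.shape[:2]
    phased_arr = np.broadcast_to(np.asarray(phased, bool), (N, M))
    miss = np.zeros((N, M), bool) if missing is None else np.asarray(missing, bool)

    fmt_fields = ["GT"]
    if gp is not None:
        fmt_fields.append("GP")
    if ds is not None:
        fmt_fields.append("DS")
    if pl is not None:
        fmt_fields.append("PL")
    if dp is not None:
        fmt_fields.append("DP")
    fmt = ":".join(fmt_fields)

    lines = list(_HEADER)
    if contig_length is not None:
        lines.append(f"##contig=<ID={chrom},length={contig_length}>")
    else:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for m in range(M):
        info_str = f"IMPINFO={info[m]:.6g}" if info is not None else "."
        cells = []
        for i in range(N):
            if miss[i, m]:
                g = "./."
            else:
                sep = "|" if phased_arr[i, m] else "/"
                g = f"{gt[i, m, 0]}{sep}{gt[i, m, 1]}"
            parts = [g]
            if gp is not None:
                parts.append(",".join(f"{v:.6g}" for v in gp[i, m]))
            if ds is not None:
                parts.append(f"{ds[i, m]:.6g}")
            if pl is not None:
                parts.append(",".join(str(int(v)) for v in pl[i, m]))
            if dp is not None:
                parts.append(str(int(dp[i, m])))
            cells.append(":".join(parts))
        lines.append(
            f"{chrom}\t{positions[m]}\t.\tA\tC\t.\t.\t{info_str}\t{fmt}\t" + "\t".join(cells)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, require_phased: bool = False) -> VcfData:
    """Read a minimal-dialect VCF written by :func:`write_vcf`.

    Rejects multi-allelic and INDEL records; with ``require_phased``,
    rejects unphased non-missing genotypes, reporting the offending row.
    """
    chrom = None
    samples: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gt_rows, ph_rows, gp_rows, ds_rows, pl_rows, dp_rows, info_vals = (
        [], [], [], [], [], [], []
    )
    has = {"GP": False, "DS": False, "PL": False, "DP": False}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom = chrom or f[0]
            ref, alt = f[3], f[4]
            if "," in alt:
                raise ValueError(
                    f"unsupported multi-allelic record at {f[0]}:{f[1]}"
                )
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"unsupported INDEL record at {f[0]}:{f[1]}")
            positions.append(int(f[1]))
            refs.append(ref)
            alts.append(alt)
            if f[7].startswith("IMPINFO="):
                info_vals.append(float(f[7].split("=", 1)[1]))
            else:
                info_vals.append(np.nan)
            fmt_fields = f[8].split(":")
            idx = {name: i for i, name in enumerate(fmt_fields)}
            for name in has:
                has[name] |= name in idx
            row_gt, row_ph = [], []
            row_gp, row_ds, row_pl, row_dp = [], [], [], []
            for cell in f[9:]:
                parts = cell.split(":")
                g = parts[idx["GT"]]
                if g in (".", "./.", ".|."):
                    row_gt.append((-1, -1))
                    row_ph.append(False)
                else:
                    sep = "|" if "|" in g else "/"
                    if require_phased and sep == "/":
                        raise ValueError(
                            f"unphased genotype {g!r} at {f[0]}:{f[1]}"
                        )
                    a, b = g.split(sep)
                    row_gt.append((int(a), int(b)))
                    row_ph.append(sep == "|")
                row_gp.append(
                    tuple(map(float, parts[idx["GP"]].split(","))) if "GP" in idx else (np.nan,) * 3
                )
                row_ds.append(float(parts[idx["DS"]]) if "DS" in idx else np.nan)
                row_pl.append(
                    tuple(map(int, parts[idx["PL"]].split(","))) if "PL" in idx else (0, 0, 0)
                )
                row_dp.append(int(parts[idx["DP"]]) if "DP" in idx else -1)
            gt_rows.append(row_gt)
            ph_rows.append(row_ph)
            gp_rows.append(row_gp)
            ds_rows.append(row_ds)
            pl_rows.append(row_pl)
            dp_rows.append(row_dp)
    gt = np.array(gt_rows, dtype=np.int8).transpose(1, 0, 2)  # (N, M, 2)
    return VcfData(
        chrom=chrom or "chr1",
        positions=np.array(positions, dtype=np.int64),
        samples=samples,
        gt=gt,
        phased=np.array(ph_rows, dtype=bool).T,
        gp=np.array(gp_rows).transpose(1, 0, 2) if has["GP"] else None,
        ds=np.array(ds_rows).T if has["DS"] else None,
        pl=np.array(pl_rows, dtype=np.int64).transpose(1, 0, 2) if has["PL"] else None,
        dp=np.array(dp_rows, dtype=np.int64).T if has["DP"] else None,
        info=np.array(info_vals),
        ref=np.array(refs),
        alt=np.array(alts),
    )


def gl_to_pl(gl: np.ndarray) -> np.ndarray:
    """Scaled phred likelihood triplets (standard rounding, min entry 0)."""
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(np.maximum(gl, 1e-300))
    pl = pl - pl.min(axis=-1, keepdims=True)
    return np.rint(np.minimum(pl, 255)).astype(np.int64)
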