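"""Readers and writers for the on-disk formats the pipeline touches.

Formats: PennCNV ``rawcnv`` call lists (read), PLINK ``.cnv`` (read/write),
SNP maps as TSV or PLINK ``.bim`` (read), PLINK ``.fam`` pedigrees (read),
phenotype/covariate TSV (read), BED blacklists (read, converted from 0-based
half-open to 1-based closed), association result TSV (write).

Parsers are strict: a malformed line raises :class:`ParseError` naming the
line number; nothing is silently dropped.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .types import (
    BlacklistRegion,
    CallSource,
    CnvCall,
    CnvState,
    Family,
    PhenotypeRecord,
    SnpLocus,
    chrom_sort_key,
    normalize_chrom,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file did not match its expected layout."""


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?(?:\s+endsnp=(?P<endsnp>\S+))?"
)


def _state_from_cn(cn: int, where: str) -> CnvState:
    if cn < 2:
        return CnvState.DELETION
    if cn > 2:
        return CnvState.DUPLICATION
    raise ParseError(f"{where}: cn=2 contradicts a CNV call")


def read_penncnv_calls(path: str | Path, source_tag: CallSource | str = CallSource.CALLER_B) -> list[CnvCall]:
    """Read a PennCNV-style ``rawcnv`` file.

    Each line looks like::

        chr3:53003415-53013826 numsnp=12 length=10,412 state2,cn=1 S001 startsnp=rs2336721 endsnp=rs2581795

    Copy number < 2 maps to a deletion, > 2 to a duplication; ``cn=2`` is
    rejected as contradictory. Thousands separators in the length field are
    tolerated (the field itself is redundant and not stored).
    """
    source = CallSource(source_tag)
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _RAWCNV_RE.match(line.strip())
            if m is None:
                raise ParseError(f"{path}:{lineno}: unrecognized rawcnv line: {line.strip()!r}")
            cn = int(m["cn"])
            state = _state_from_cn(cn, f"{path}:{lineno}")
            calls.append(
                CnvCall(
                    sample_id=m["sample"],
                    chrom=normalize_chrom(m["chrom"]),
                    start_bp=int(m["start"]),
                    end_bp=int(m["end"]),
                    state=state,
                    num_snps=int(m["numsnp"].replace(",", "")),
                    copy_number=cn,
                    source=source,
                )
            )
    return calls


_PLINK_CNV_HEADER = ["FID", "IID", "CHR", "BP1", "BP2", "TYPE", "SCORE", "SITES"]


def read_plink_cnv(path: str | Path, source_tag: CallSource | str = CallSource.CONSENSUS) -> list[CnvCall]:
    """Read a PLINK ``.cnv`` segment file (TYPE column = integer copy number)."""
    source = CallSource(source_tag)
    calls: list[CnvCall] = []
    with open(path) as fh:
        header = fh.readline().split()
        if header != _PLINK_CNV_HEADER:
            raise ParseError(f"{path}: expected header {' '.join(_PLINK_CNV_HEADER)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
            _fid, iid, chrom, bp1, bp2, cn, _score, sites = fields
            try:
                chrom = normalize_chrom(chrom)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            start, end, cn_i = int(bp1), int(bp2), int(cn)
            if start > end:
                raise ParseError(f"{path}:{lineno}: BP1 > BP2")
            state = _state_from_cn(cn_i, f"{path}:{lineno}")
            calls.append(
                CnvCall(
                    sample_id=iid,
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    state=state,
                    num_snps=int(sites),
                    copy_number=cn_i,
                    source=source,
                )
            )
    return calls


def write_plink_cnv(
    calls: Iterable[CnvCall],
    path: str | Path,
    family_of: Optional[dict[str, str]] = None,
) -> None:
    """Write calls as PLINK ``.cnv``. ``family_of`` maps sample to FID
    (defaults to the sample id). Copy number defaults to 1 for deletions and
    3 for duplications when a call carries none."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PLINK_CNV_HEADER) + "\n")
        for c in calls:
            fid = (family_of or {}).get(c.sample_id, c.sample_id)
            cn = c.copy_number
            if cn is None:
                cn = 1 if c.state is CnvState.DELETION else 3
            fh.write(
                f"{fid}\t{c.sample_id}\t{c.chrom[3:]}\t{c.start_bp}\t{c.end_bp}"
                f"\t{cn}\t0\t{c.num_snps}\n"
            )


def read_snp_map(path: str | Path) -> list[SnpLocus]:
    """Read a SNP/probe map.

    Accepts a TSV with a ``snp_id``/``chrom``/``position`` header, or a PLINK
    ``.bim`` (6 whitespace-separated columns, no header; columns 2, 1, 4).
    Loci are returned sorted by (chromosome, position); duplicate SNP ids are
    rejected.
    """
    path = Path(path)
    loci: list[SnpLocus] = []
    with open(path) as fh:
        first = fh.readline()
        fields = first.split()
        is_bim = len(fields) == 6 and "snp_id" not in first
        if is_bim:
            lines = [first] + fh.readlines()
            for lineno, line in enumerate(lines, start=1):
                if not line.strip():
                    continue
                f = line.split()
                if len(f) != 6:
                    raise ParseError(f"{path}:{lineno}: expected 6 .bim columns")
                loci.append(_make_locus(f[1], f[0], f[3], path, lineno))
        else:
            header = [h.strip() for h in first.rstrip("\n").split("\t")]
            try:
                idx = {k: header.index(k) for k in ("snp_id", "chrom", "position")}
            except ValueError as exc:
                raise ParseError(f"{path}: missing snp map column: {exc}") from exc
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                loci.append(_make_locus(f[idx["snp_id"]], f[idx["chrom"]], f[idx["position"]], path, lineno))
    seen: set[str] = set()
    for locus in loci:
        if locus.snp_id in seen:
            raise ParseError(f"{path}: duplicate snp_id {locus.snp_id}")
        seen.add(locus.snp_id)
    loci.sort(key=lambda s: (chrom_sort_key(s.chrom), s.position_bp))
    return loci


def _make_locus(snp_id: str, chrom: str, pos: str, path: Path, lineno: int) -> SnpLocus:
    try:
        position = int(pos)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer position {pos!r}") from exc
    return SnpLocus(snp_id=snp_id, chrom=normalize_chrom(chrom), position_bp=position)


def read_pedigree(path: str | Path) -> list[Family]:
    """Read a PLINK ``.fam`` file (FID IID PAT MAT SEX PHENO) into sibships.

    Rows sharing a family ID become one :class:`Family`; parental ID columns
    are ignored (the association test permutes among siblings only).
    """
    members: dict[str, list[str]] = {}
    sexes: dict[str, dict[str, int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 .fam columns")
            fid, iid, _pat, _mat, sex, _pheno = f[:6]
            if fid not in members:
                members[fid] = []
                sexes[fid] = {}
                order.append(fid)
            if iid in members[fid]:
                raise ParseError(f"{path}:{lineno}: duplicate individual {iid} in family {fid}")
            members[fid].append(iid)
            try:
                sexes[fid][iid] = int(sex)
            except ValueError:
                sexes[fid][iid] = 0
    return [Family(family_id=fid, member_ids=members[fid], sex=sexes[fid]) for fid in order]


_PHENO_COLUMNS = {
    "trait": None,  # chosen per call
    "age": "age",
    "sex": "sex",
    "bmi": "bmi",
    "ethnicity": "ethnicity",
    "site": "site",
    "hypertension": "hypertension",
    "diabetes": "diabetes",
}


def read_phenotypes(path: str | Path, trait: str = "FPG") -> list[PhenotypeRecord]:
    """Read a phenotype/covariate TSV with named columns.

    Requires a ``sample_id`` column and the chosen trait column; recognizes
    ``age``, ``sex``, ``bmi``, ``ethnicity``, ``site``, ``hypertension`` and
    ``diabetes``. Empty cells become missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    if trait not in df.columns:
        raise ParseError(f"{path}: missing trait column {trait!r}")

    def opt(row, col, cast):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    records = []
    for _, row in df.iterrows():
        records.append(
            PhenotypeRecord(
                sample_id=str(row["sample_id"]),
                trait_value=opt(row, trait, float),
                age=opt(row, "age", float),
                sex=opt(row, "sex", lambda v: int(float(v))),
                bmi=opt(row, "bmi", float),
                ethnicity=opt(row, "ethnicity", str),
                site=opt(row, "site", str),
                hypertension=opt(row, "hypertension", lambda v: int(float(v))),
                diabetes=opt(row, "diabetes", lambda v: bool(int(float(v)))),
            )
        )
    return records


def read_blacklist_bed(path: str | Path) -> list[BlacklistRegion]:
    """Read a BED file of blacklist regions, converting 0-based half-open
    records to the internal 1-based closed convention."""
    regions: list[BlacklistRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = normalize_chrom(f[0])
            start0, end0 = int(f[1]), int(f[2])
            if start0 >= end0:
                raise ParseError(f"{path}:{lineno}: empty or inverted BED interval")
            regions.append(
                BlacklistRegion(
                    chrom=chrom,
                    start_bp=start0 + 1,
                    end_bp=end0,
                    label=f[3] if len(f) > 3 else "",
                )
            )
    return regions


def write_assoc_results(results, path: str | Path) -> None:
    """Write association results as a TSV mirroring the standard report
    layout (SNP, chromosome, position, state, frequency, counts, statistic,
    raw/adjusted p, FDR)."""
    rows = []
    for r in results:
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "position": r.position_bp,
                "state": r.state_tested.value,
                "frequency": r.frequency,
                "n_carriers": r.n_carriers,
                "n_normal": r.n_normal,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "fdr": r.fdr,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sample_family_index(families: Iterable[Family]) -> dict[str, str]:
    """Map sample id -> family id, rejecting samples listed in two families."""
    index: dict[str, str] = {}
    for fam in families:
        for sid in fam.member_ids:
            if sid in index:
                raise ValueError(f"sample {sid} appears in families {index[sid]} and {fam.family_id}")
            index[sid] = fam.family_id
    return index
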