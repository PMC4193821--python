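"""Reading and writing trio genotype data, exposure tables, and result tables.

Genotypes are held as per-marker minor-allele dosages (0, 1, 2) with a
``MISSING`` sentinel of -1.  A trio is an affected child plus both biological
parents; maternal exposures are binary attributes of the mother shared by the
whole trio.  The interchange format is the whitespace-delimited PLINK
.ped/.map dialect: columns FID IID PAT MAT SEX PHENO followed by two allele
columns per marker, with "0" as the missing-allele code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an absent genotype dosage or exposure value.
MISSING: int = -1

#: Exposure table entries accepted as "value absent".
EXPOSURE_NA_CODES = ("", "NA", "-9")

RESULT_COLUMNS = [
    "snp_id", "model", "term", "beta", "se", "wald_p",
    "lrt_stat", "lrt_df", "lrt_p", "bonferroni_p",
    "stratum", "or", "ci_lo", "ci_hi", "n_sets",
]


class TrioFormatError(ValueError):
    """Malformed trio genotype or exposure input."""


@dataclass
class Marker:
    """One biallelic variant on the panel.

    ``allele_minor``/``allele_major`` are provisional after reading (assigned
    lexicographically) until QC fixes the minor allele from parental
    frequencies.  A marker with no second allele observed carries '.' as a
    placeholder minor allele.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise TrioFormatError(f"{self.snp_id}: pos_bp must be >= 1")
        if self.allele_minor == self.allele_major:
            raise TrioFormatError(f"{self.snp_id}: identical alleles")


@dataclass
class TrioRecord:
    """One family: father/mother/child dosage vectors plus maternal exposures.

    All three vectors share the panel's marker order.  Exposure values are
    0, 1 or ``MISSING``.
    """

    family_id: str
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    exposures: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.father) == len(self.mother) == len(self.child)):
            raise TrioFormatError(
                f"family {self.family_id}: genotype vectors differ in length")

    @property
    def n_markers(self) -> int:
        return len(self.child)


@dataclass
class ResultRow:
    """One line of a per-SNP result table (long format)."""

    snp_id: str
    model: str
    term: str = ""
    beta: float = np.nan
    se: float = np.nan
    wald_p: float = np.nan
    lrt_stat: float = np.nan
    lrt_df: int | float = np.nan
    lrt_p: float = np.nan
    bonferroni_p: float = np.nan
    stratum: str = ""
    or_value: float = np.nan
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    n_sets: int | float = np.nan


def _parse_map(map_path) -> list[tuple[str, str, int]]:
    out = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == 4:
                chrom, snp_id, _cm, pos = tok
            elif len(tok) == 3:
                chrom, snp_id, pos = tok
            else:
                raise TrioFormatError(f"{map_path}:{ln}: expected 3 or 4 columns")
            out.append((chrom, snp_id, int(pos)))
    return out


def read_ped_map(ped_path, map_path) -> tuple[list[Marker], list[TrioRecord]]:
    """Read a trio panel from PLINK-style .ped/.map files.

    Each family must contribute exactly three rows: two parents and one
    child whose PAT/MAT columns point at the parents' IIDs.  Dosages count
    copies of the lexicographically smaller observed allele; QC later flips
    them where that allele is not the minor one.  A third allele at any
    marker is a hard error naming the SNP.
    """
    sites = _parse_map(map_path)
    n_mark = len(sites)

    rows: dict[str, list[list[str]]] = {}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_mark:
                raise TrioFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_mark} fields, got {len(tok)}")
            rows.setdefault(tok[0], []).append(tok)

    # collect the allele inventory per marker
    alleles: list[set[str]] = [set() for _ in range(n_mark)]
    for fam_rows in rows.values():
        for tok in fam_rows:
            for j in range(n_mark):
                for a in tok[6 + 2 * j: 8 + 2 * j]:
                    if a != "0":
                        alleles[j].add(a)
    markers: list[Marker] = []
    seen_ids: set[str] = set()
    for (chrom, snp_id, pos), obs in zip(sites, alleles):
        if snp_id in seen_ids:
            raise TrioFormatError(f"duplicate SNP id {snp_id}")
        seen_ids.add(snp_id)
        if len(obs) > 2:
            raise TrioFormatError(
                f"marker {snp_id} has more than two alleles: {sorted(obs)}")
        srt = sorted(obs)
        if len(srt) == 2:
            minor, major = srt
        elif len(srt) == 1:
            minor, major = ".", srt[0]
        else:
            minor, major = ".", "?"
        markers.append(Marker(snp_id, chrom, pos, minor, major))

    trios: list[TrioRecord] = []
    for fid, fam_rows in rows.items():
        if len(fam_rows) != 3:
            raise TrioFormatError(
                f"family {fid}: expected 3 members, found {len(fam_rows)}")
        by_iid = {tok[1]: tok for tok in fam_rows}
        if len(by_iid) != 3:
            raise TrioFormatError(f"family {fid}: duplicated individual ids")
        children = [tok for tok in fam_rows if tok[2] != "0" and tok[3] != "0"]
        if len(children) != 1:
            raise TrioFormatError(
                f"family {fid}: ambiguous proband "
                f"({len(children)} members with both parents listed)")
        child = children[0]
        if child[2] not in by_iid or child[3] not in by_iid:
            raise TrioFormatError(f"family {fid}: parent of proband absent")
        father, mother = by_iid[child[2]], by_iid[child[3]]
        if father[1] == mother[1]:
            raise TrioFormatError(f"family {fid}: duplicated parental role")

        def _dosages(tok) -> np.ndarray:
            d = np.empty(n_mark, dtype=np.int8)
            for j, mk in enumerate(markers):
                a1, a2 = tok[6 + 2 * j], tok[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    d[j] = MISSING
                    continue
                for a in (a1, a2):
                    if a not in (mk.allele_minor, mk.allele_major):
                        raise TrioFormatError(
                            f"marker {mk.snp_id}: unexpected allele {a}")
                d[j] = (a1 == mk.allele_minor) + (a2 == mk.allele_minor)
            return d

        trios.append(TrioRecord(fid, _dosages(father), _dosages(mother),
                                _dosages(child)))
    return markers, trios


def write_ped_map(markers: list[Marker], trios: list[TrioRecord],
                  ped_path, map_path) -> None:
    """Write trios back out in the same .ped/.map dialect (round-trip safe)."""
    with open(map_path, "w") as fh:
        for mk in markers:
            fh.write(f"{mk.chrom}\t{mk.snp_id}\t0\t{mk.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for tr in trios:
            members = [
                (f"{tr.family_id}_F", "0", "0", "1", tr.father),
                (f"{tr.family_id}_M", "0", "0", "2", tr.mother),
                (f"{tr.family_id}_C", f"{tr.family_id}_F", f"{tr.family_id}_M",
                 "0", tr.child),
            ]
            for iid, pat, mat, sex, dos in members:
                cells = [tr.family_id, iid, pat, mat, sex, "2"]
                for mk, d in zip(markers, dos):
                    if d == MISSING:
                        cells += ["0", "0"]
                    else:
                        minor = mk.allele_minor if mk.allele_minor != "." else "?"
                        cells += [minor] * int(d) + [mk.allele_major] * (2 - int(d))
                fh.write(" ".join(cells) + "\n")


def read_exposures(csv_path, exposure_names: list[str]) -> dict[str, dict[str, int]]:
    """Parse a maternal-exposure CSV into family_id -> {exposure: 0/1/MISSING}.

    The first column is the family id (any header name); every requested
    exposure must appear as a column.  Accepted missing codes: empty string,
    "NA", "-9".  Anything else outside {0, 1} is an error reporting the row.
    """
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    for name in exposure_names:
        if name not in df.columns:
            raise TrioFormatError(f"exposure column absent: {name}")
    df = df.reset_index(drop=True)
    table: dict[str, dict[str, int]] = {}
    for i in range(len(df)):  # header is line 1, data starts at line 2
        fid = str(df.at[i, id_col]).strip()
        rec: dict[str, int] = {}
        for name in exposure_names:
            raw = str(df.at[i, name]).strip()
            if raw in EXPOSURE_NA_CODES:
                rec[name] = MISSING
            elif raw in ("0", "1"):
                rec[name] = int(raw)
            else:
                raise TrioFormatError(
                    f"{csv_path}: row {i + 2}: invalid exposure value {raw!r} "
                    f"for {name}")
        table[fid] = rec
    return table


def attach_exposures(trios: list[TrioRecord],
                     table: dict[str, dict[str, int]]) -> list[str]:
    """Merge an exposure table into trios in place.

    Returns the family ids present in the table but not among the trios;
    trios absent from the table get MISSING for every exposure in it.
    """
    names = sorted({n for rec in table.values() for n in rec})
    fids = set()
    for tr in trios:
        fids.add(tr.family_id)
        rec = table.get(tr.family_id)
        for n in names:
            tr.exposures[n] = rec[n] if rec is not None else MISSING
    return [fid for fid in table if fid not in fids]


def tabulate_exposures(trios: list[TrioRecord],
                       exposure_names: list[str]) -> pd.DataFrame:
    """Per-exposure counts: n exposed, % exposed, n missing.

    The percentage denominator is the number of trios with a non-missing
    value for that exposure, rounded to one decimal.
    """
    rows = []
    for name in exposure_names:
        vals = [tr.exposures.get(name, MISSING) for tr in trios]
        n_missing = sum(v == MISSING for v in vals)
        n_known = len(vals) - n_missing
        n_exposed = sum(v == 1 for v in vals)
        pct = round(100.0 * n_exposed / n_known, 1) if n_known else np.nan
        rows.append({"exposure": name, "n_trios": len(vals),
                     "n_exposed": n_exposed, "n_known": n_known,
                     "pct_exposed": pct, "n_missing": n_missing})
    return pd.DataFrame(rows).set_index("exposure")


def results_to_frame(rows: list[ResultRow]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "snp_id": r.snp_id, "model": r.model, "term": r.term,
        "beta": r.beta, "se": r.se, "wald_p": r.wald_p,
        "lrt_stat": r.lrt_stat, "lrt_df": r.lrt_df, "lrt_p": r.lrt_p,
        "bonferroni_p": r.bonferroni_p, "stratum": r.stratum,
        "or": r.or_value, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
        "n_sets": r.n_sets,
    } for r in rows], columns=RESULT_COLUMNS)
    return df


def write_results_tsv(rows: list[ResultRow], path) -> None:
    """Write results in the fixed column order, 6 significant digits."""
    df = results_to_frame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
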