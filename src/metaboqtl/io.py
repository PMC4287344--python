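"""Readers and writers for the plain-text interchange formats.

Pedigrees travel as FAM-style text (with the household label in the sixth
column), genotypes as a minimal VCF (GT:DS) or a dosage TSV plus variant
metadata TSV, spectra as two-column (ppm, intensity) TSV written with ppm
descending (the display convention; axes are ascending in memory), and
phenotypes / kinship / results as ordinary TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .genotypes import GenotypeMatrix
from .nmr import Spectrum
from .pedigree import MISSING, FEMALE, MALE, KinshipMatrix, Pedigree
from .spectra import SpectrumSet

_SEX_OUT = {MALE: "1", FEMALE: "2"}
_SEX_IN = {"1": MALE, "2": FEMALE}


def write_fam(ped: Pedigree, path: str, family_id: str = "FAM1") -> None:
    """FAM-style text: family, individual, father, mother, sex, household."""
    with open(path, "w") as fh:
        for iid, row in ped.table.iterrows():
            fh.write(
                "\t".join(
                    [
                        family_id,
                        str(iid),
                        row["father"] or "0",
                        row["mother"] or "0",
                        _SEX_OUT[row["sex"]],
                        str(row["household"]),
                    ]
                )
                + "\n"
            )


def read_fam(path: str) -> Pedigree:
    """Read FAM-style text; generations are reconstructed from the links."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["fam", "iid", "father", "mother", "sex", "household"],
        dtype=str,
    )
    df["father"] = df["father"].replace("0", MISSING).fillna(MISSING)
    df["mother"] = df["mother"].replace("0", MISSING).fillna(MISSING)
    df["sex"] = df["sex"].map(_SEX_IN)
    if df["sex"].isna().any():
        raise InvalidArgumentError("sex column must be 1 (male) or 2 (female)")
    df = df.set_index("iid")

    gen: dict[str, int] = {}

    def depth(iid: str, seen: tuple = ()) -> int:
        if iid in gen:
            return gen[iid]
        if iid in seen:
            raise InvalidArgumentError("cyclic parent links in FAM file")
        fa, mo = df.loc[iid, "father"], df.loc[iid, "mother"]
        g = 0 if fa == MISSING else 1 + max(
            depth(fa, seen + (iid,)), depth(mo, seen + (iid,))
        )
        gen[iid] = g
        return g

    df["generation"] = [depth(i) for i in df.index]
    return Pedigree(df[["father", "mother", "sex", "household", "generation"]])


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_tsv(G: GenotypeMatrix, dosage_path: str, variants_path: str) -> None:
    pd.DataFrame(
        G.dosages, index=pd.Index(G.sample_ids, name="iid"), columns=G.variants["id"]
    ).to_csv(dosage_path, sep="\t")
    G.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path: str, variants_path: str) -> GenotypeMatrix:
    d = pd.read_csv(dosage_path, sep="\t", index_col=0)
    v = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    return GenotypeMatrix(d.to_numpy(float), v, tuple(d.index.astype(str)))


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Minimal VCF 4.2 with GT (rounded dosage) and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in G.variants.iterrows():
            cells = []
            for d in G.dosages[:, j]:
                if not np.isfinite(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(round(d))]}:{d:g}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['a2']}\t{row['a1']}"
                f"\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF via cyvcf2; DS is used when present, else GT allele counts.

    The effect allele (a1) is ALT, matching :func:`write_vcf`.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = tuple(vcf.samples)
    cols, meta = [], []
    for rec in vcf:
        try:
            ds = rec.format("DS")
            dosage = np.asarray(ds, float).reshape(-1)
        except (KeyError, TypeError):
            gts = np.asarray(rec.gt_types, float)  # 0 hom-ref, 1 het, 3 hom-alt
            dosage = np.where(gts == 3, 2.0, gts)
            dosage[gts == 2] = np.nan  # unknown
        cols.append(dosage)
        freq = np.nanmean(dosage) / 2.0
        meta.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "a1": rec.ALT[0] if rec.ALT else ".",
                "a2": rec.REF,
                "maf": float(min(freq, 1 - freq)),
                "block": "",
            }
        )
    return GenotypeMatrix(np.column_stack(cols), pd.DataFrame(meta), samples)


# ---------------------------------------------------------------------------
# spectra


def write_spectrum(s: Spectrum, path: str) -> None:
    """Two-column TSV, ppm descending (display convention)."""
    pd.DataFrame({"ppm": s.ppm[::-1], "intensity": s.intensity[::-1]}).to_csv(
        path, sep="\t", index=False
    )


def read_spectrum(path: str, kind: str = "jres") -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(), kind=kind)


def write_spectrum_set(sset: SpectrumSet, directory: str) -> None:
    """One file per sample per spectrum type: <sample>.<kind>.tsv"""
    os.makedirs(directory, exist_ok=True)
    for i, sid in enumerate(sset.sample_ids):
        write_spectrum(sset.cpmg_spectrum(i), os.path.join(directory, f"{sid}.cpmg.tsv"))
        write_spectrum(sset.jres_spectrum(i), os.path.join(directory, f"{sid}.jres.tsv"))


def read_spectrum_set(directory: str) -> SpectrumSet:
    files = sorted(f for f in os.listdir(directory) if f.endswith(".cpmg.tsv"))
    if not files:
        raise InvalidArgumentError(f"no *.cpmg.tsv files in {directory}")
    sample_ids, cpmg, jres = [], [], []
    ppm = None
    for f in files:
        sid = f[: -len(".cpmg.tsv")]
        c = read_spectrum(os.path.join(directory, f), kind="cpmg")
        j = read_spectrum(os.path.join(directory, f"{sid}.jres.tsv"), kind="jres")
        if ppm is None:
            ppm = c.ppm
        sample_ids.append(sid)
        cpmg.append(c.intensity)
        jres.append(j.intensity)
    return SpectrumSet(ppm, np.array(cpmg), np.array(jres), tuple(sample_ids))


# ---------------------------------------------------------------------------
# kinship and phenotypes


def write_kinship(K: KinshipMatrix, path: str) -> None:
    pd.DataFrame(K.values, index=K.ids, columns=K.ids).to_csv(path, sep="\t")


def read_kinship(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(float), tuple(df.index.astype(str)))


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
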