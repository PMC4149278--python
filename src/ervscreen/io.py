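"""File formats: FASTA via Biopython, tab-separated tables via pandas.

All tables are TSV with a header row, UTF-8. Coordinates in the locus table
are 0-based half-open (stated in a leading comment line of the file).
FASTA sequences are normalized to upper case on read; wrapped and
mixed-case records round-trip to the same canonical form.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .pcr_genotyping import PrimerSet
from .synthetic_data import Individual, ProviralLocus, ReferencePanel
from .virtual_digest import Enzyme

LOCUS_COLUMNS = [
    "locus_id", "contig", "insertion_point", "strand",
    "element_id", "repertoire", "tsd_length",
]


def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DataError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Mapping[str, str], width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_tsv(path, df: pd.DataFrame, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_locus_table(path, loci: Sequence[ProviralLocus]) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id, "contig": l.contig,
                "insertion_point": l.insertion_point, "strand": l.strand,
                "element_id": l.element_id,
                "repertoire": ",".join(sorted(l.repertoire)),
                "tsd_length": l.tsd_length,
            }
            for l in loci
        ],
        columns=LOCUS_COLUMNS,
    )
    write_tsv(path, df, comment="coordinates are 0-based, half-open")


def read_locus_table(path, host_genome: Mapping[str, str] | None = None):
    df = read_tsv(path, required=LOCUS_COLUMNS)
    loci = []
    for i, row in df.iterrows():
        try:
            locus = ProviralLocus(
                locus_id=str(row.locus_id),
                contig=str(row.contig),
                insertion_point=int(row.insertion_point),
                strand=str(row.strand),
                element_id=str(row.element_id),
                repertoire=frozenset(str(row.repertoire).split(",")),
                tsd_length=int(row.tsd_length),
            )
        except (ValueError, DataError) as exc:
            raise DataError(f"{path} line {i + 2}: {exc}") from exc
        if host_genome is not None:
            if locus.contig not in host_genome:
                raise DataError(
                    f"{path}: locus {locus.locus_id} references unknown "
                    f"contig {locus.contig!r}"
                )
            if not 0 <= locus.insertion_point < len(host_genome[locus.contig]):
                raise DataError(
                    f"{path}: locus {locus.locus_id} insertion_point "
                    f"{locus.insertion_point} outside contig {locus.contig!r}"
                )
        loci.append(locus)
    return loci


def read_enzyme_table(path) -> list[Enzyme]:
    df = read_tsv(path, required=["name", "site", "cut_offset"])
    return [
        Enzyme(str(r.name), str(r.site), int(r.cut_offset))
        for r in df.itertuples(index=False)
    ]


def write_enzyme_table(path, enzymes: Sequence[Enzyme]) -> None:
    df = pd.DataFrame(
        [{"name": e.name, "site": e.site, "cut_offset": e.cut_offset}
         for e in enzymes]
    )
    write_tsv(path, df)


PRIMER_COLUMNS = [
    "locus_id", "forward_I", "reverse_I", "forward_II", "reverse_II",
    "size_I", "size_II_solo", "size_II_pre",
]


def read_primer_table(path) -> dict[str, PrimerSet]:
    df = read_tsv(path, required=PRIMER_COLUMNS)
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.locus_id)] = PrimerSet(
            locus_id=str(r.locus_id),
            forward_I=str(r.forward_I), reverse_I=str(r.reverse_I),
            forward_II=str(r.forward_II), reverse_II=str(r.reverse_II),
            size_I=int(r.size_I),
            size_II_solo=int(r.size_II_solo),
            size_II_pre=int(r.size_II_pre),
        )
    return out


def write_primer_table(path, primer_sets: Mapping[str, PrimerSet]) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": p.locus_id,
                "forward_I": p.forward_I, "reverse_I": p.reverse_I,
                "forward_II": p.forward_II, "reverse_II": p.reverse_II,
                "size_I": p.size_I, "size_II_solo": p.size_II_solo,
                "size_II_pre": p.size_II_pre,
            }
            for p in primer_sets.values()
        ],
        columns=PRIMER_COLUMNS,
    )
    write_tsv(path, df)


def write_panel(outdir, panel: ReferencePanel) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "host.fasta", panel.host_genome)
    write_fasta(
        outdir / "elements.fasta",
        {e.element_id: e.seq for e in panel.elements},
    )
    meta = pd.DataFrame(
        [
            {
                "element_id": e.element_id,
                "ltr5_start": e.ltr5[0], "ltr5_end": e.ltr5[1],
                "ltr3_start": e.ltr3[0], "ltr3_end": e.ltr3[1],
                "identity": e.identity,
                "is_reference": e.element_id == panel.reference_id,
            }
            for e in panel.elements
        ]
    )
    write_tsv(outdir / "elements.tsv",
              meta, comment="coordinates are 0-based, half-open")
    write_locus_table(outdir / "loci.tsv", panel.loci)


def read_panel(outdir) -> ReferencePanel:
    outdir = Path(outdir)
    host = read_fasta(outdir / "host.fasta")
    seqs = read_fasta(outdir / "elements.fasta")
    meta = read_tsv(outdir / "elements.tsv",
                    required=["element_id", "ltr5_start", "ltr5_end",
                              "ltr3_start", "ltr3_end", "identity",
                              "is_reference"])
    from .synthetic_data import ProviralElement

    elements, reference_id = [], None
    for r in meta.itertuples(index=False):
        eid = str(r.element_id)
        elements.append(
            ProviralElement(
                eid, seqs[eid],
                (int(r.ltr5_start), int(r.ltr5_end)),
                (int(r.ltr3_start), int(r.ltr3_end)),
                float(r.identity),
            )
        )
        if bool(r.is_reference):
            reference_id = eid
    if reference_id is None:
        raise DataError(f"{outdir}: no reference element flagged")
    loci = read_locus_table(outdir / "loci.tsv", host_genome=host)
    panel = ReferencePanel(host, elements, loci, reference_id)
    panel.validate()
    return panel


def write_genotype_matrix(path, cohort: Sequence[Individual],
                          loci: Sequence[ProviralLocus]) -> None:
    rows = []
    for ind in cohort:
        row = {"individual_id": ind.individual_id, "group": ind.group}
        for loc in loci:
            row[loc.locus_id] = "/".join(ind.genotypes[loc.locus_id])
        rows.append(row)
    write_tsv(path, pd.DataFrame(rows))


def read_genotype_matrix(path) -> list[Individual]:
    df = read_tsv(path, required=["individual_id", "group"])
    loci = [c for c in df.columns if c not in ("individual_id", "group")]
    out = []
    for r in df.itertuples(index=False):
        geno = {
            lid: tuple(getattr(r, lid).split("/")) for lid in loci
        }
        out.append(Individual(str(r.individual_id), str(r.group), geno))
    return out


def canonical_fasta_bytes(records: Mapping[str, str]) -> bytes:
    buf = _io.StringIO()
    for name, seq in records.items():
        SeqIO.write([SeqRecord(Seq(seq.upper()), id=name, description="")],
                    buf, "fasta")
    return buf.getvalue().encode()
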