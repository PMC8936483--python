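"""Readers and writers: haplotype datasets, ATS archives, exports.

Datasets travel as TSV (a comment line with dimensions, a header row of
segregating-site positions, one 0/1 row per haplotype) or as biallelic VCF
with an ancestral-allele ``AA`` INFO field.  An ATS is archived as a
directory of four TSV tables (nodes, branches, recombinations, mutations)
that round-trips bit-stably; a lossy tskit export of the node/edge/mutation
tables is provided for interoperability.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .ats import (ANCESTRAL, ATS, COMMON_ANCESTOR, MutationRecord,
                  RecombinationRecord, SAMPLE)
from .dataset import Dataset

__all__ = ["read_dataset", "write_dataset", "read_ats", "write_ats",
           "to_tree_sequence", "write_tmrca_bed"]


# -- datasets ---------------------------------------------------------------

def write_dataset(data: Dataset, path) -> None:
    """Write a dataset as TSV: positions header + one 0/1 row per sample."""
    pos = data.positions
    with open(path, "w") as fh:
        fh.write(f"#n={data.n}\tL={data.L}\n")
        fh.write("\t".join(str(p) for p in pos) + "\n")
        mat = data.matrix(segregating_only=True)
        for row in mat:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def _read_matrix_tsv(path) -> Dataset:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#n=..\\tL=..' header line")
        meta = dict(kv.split("=") for kv in header[1:].split("\t"))
        n, L = int(meta["n"]), int(meta["L"])
        posline = fh.readline().strip()
        positions = [int(p) for p in posline.split("\t")] if posline else []
        rows = []
        for line in fh:
            line = line.strip()
            if line:
                rows.append([int(v) for v in line.split("\t")])
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} haplotype rows, got {len(rows)}")
    mat = np.array(rows, dtype=np.int8).reshape(n, len(positions))
    return Dataset.from_matrix(mat, positions=positions, L=L)


def _read_vcf(path, L=None) -> Dataset:
    """Biallelic VCF with an ``AA`` INFO field naming the ancestral allele.

    The ancestral allele maps to 0 regardless of REF/ALT; positions are
    converted to 0-based site indices.  Haploid or phased diploid genotypes
    are accepted (each phased allele becomes one haplotype).
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    n_hap = None
    seg = {}
    contig_len = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig") and "length=" in line:
            contig_len = int(line.split("length=")[1].rstrip(">").split(",")[0])
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"site at position {v.POS}: multiallelic records are not "
                "supported (infinite-sites model)")
        aa = dict(v.INFO).get("AA")
        if aa is None:
            raise ValueError(f"site at position {v.POS}: missing AA "
                             "(ancestral allele) INFO field")
        alleles = [v.REF] + v.ALT
        if aa not in alleles:
            raise ValueError(f"site at position {v.POS}: ancestral allele "
                             f"{aa!r} is neither REF nor ALT")
        hap_alleles = []
        for g in v.genotypes:
            hap_alleles.extend(g[:-1])
        if n_hap is None:
            n_hap = len(hap_alleles)
        carriers = frozenset(i for i, a in enumerate(hap_alleles)
                             if alleles[a] != aa)
        if carriers:
            seg[v.POS - 1] = carriers
    if n_hap is None:
        raise ValueError(f"{path}: no variant records")
    if L is None:
        L = contig_len if contig_len is not None else max(seg, default=0) + 1
    return Dataset(n=n_hap, L=int(L), seg=seg)


def read_dataset(path, fmt: str = "matrix-tsv", L=None) -> Dataset:
    """Read a dataset (``fmt`` in {"matrix-tsv", "vcf"})."""
    if fmt == "matrix-tsv":
        return _read_matrix_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path, L=L)
    raise ValueError(f"unknown dataset format {fmt!r}")


# -- ATS archives -----------------------------------------------------------

_F = "%.17g"  # bit-stable float formatting


def write_ats(ats: ATS, path) -> None:
    """Archive an ATS as four TSV tables in directory ``path``."""
    os.makedirs(path, exist_ok=True)
    an = ats._require_valid()
    with open(os.path.join(path, "nodes.tsv"), "w") as fh:
        fh.write(f"#L={ats.L}\tn={ats.n}\n")
        fh.write("id\ttime\tkind\n")
        for u in sorted(ats.node_time):
            fh.write(f"{u}\t{_F % ats.node_time[u]}\t{ats.node_kind[u]}\n")
    with open(os.path.join(path, "branches.tsv"), "w") as fh:
        fh.write("child\tparent\tleft\tright\n")
        for u in sorted(an.mat):
            slot = an.parent_slot[u]
            for l, r, _ in an.mat[u]:
                if slot[0] == "ca":
                    fh.write(f"{u}\t{slot[1]}\t{l}\t{r}\n")
                else:
                    rec = ats.recs[slot[1]]
                    bnd = rec.breakpoint + 1
                    if l < bnd:
                        fh.write(f"{u}\t{rec.left_parent}\t{l}\t{min(r, bnd)}\n")
                    if r > bnd:
                        fh.write(f"{u}\t{rec.right_parent}\t{max(l, bnd)}\t{r}\n")
    with open(os.path.join(path, "recombinations.tsv"), "w") as fh:
        fh.write("child\tbreakpoint\tleft_parent\tright_parent\n")
        for rec in sorted(ats.recs, key=lambda r: r.left_parent):
            fh.write(f"{rec.child}\t{rec.breakpoint}\t{rec.left_parent}"
                     f"\t{rec.right_parent}\n")
    with open(os.path.join(path, "mutations.tsv"), "w") as fh:
        fh.write("site\tbranch_child\n")
        for m in (ats.mutations or []):
            fh.write(f"{m.site}\t{m.branch}\n")


def read_ats(path, data: "Dataset | None" = None) -> ATS:
    """Load an ATS archive written by :func:`write_ats`.

    The branch table is re-derived from the event tables and must agree
    with the archive (bit-stable round trip); a dataset may be supplied to
    re-attach carrier sets to the mutation table.
    """
    for name in ("nodes.tsv", "branches.tsv", "recombinations.tsv",
                 "mutations.tsv"):
        if not os.path.exists(os.path.join(path, name)):
            raise ValueError(f"ATS archive {path} is missing {name}")
    with open(os.path.join(path, "nodes.tsv")) as fh:
        meta = dict(kv.split("=") for kv in fh.readline()[1:].strip().split("\t"))
        nodes = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    L, n = int(meta["L"]), int(meta["n"])
    ats = ATS(L, n)
    for _, row in nodes.iterrows():
        u, t, kind = int(row["id"]), float(row["time"]), row["kind"]
        if kind == SAMPLE:
            if u >= n or t != 0.0:
                raise ValueError(f"corrupt archive: bad sample node {u}")
        else:
            ats._new_node_with_id(u, t, kind)
    recs = pd.read_csv(os.path.join(path, "recombinations.tsv"), sep="\t")
    for _, row in recs.iterrows():
        ats.recs.append(RecombinationRecord(int(row["child"]),
                                            int(row["breakpoint"]),
                                            int(row["left_parent"]),
                                            int(row["right_parent"])))
    branches = pd.read_csv(os.path.join(path, "branches.tsv"), sep="\t")
    rec_parents = {r.left_parent for r in ats.recs} | \
                  {r.right_parent for r in ats.recs}
    for parent, group in branches.groupby("parent"):
        parent = int(parent)
        if parent in rec_parents:
            continue
        children = sorted(set(int(c) for c in group["child"]))
        if ats.node_kind.get(parent) != COMMON_ANCESTOR or len(children) != 2:
            raise ValueError(f"corrupt archive: CA node {parent}")
        ats.ca_children[parent] = tuple(children)
    ats._an = None
    violations = ats.validate()
    if violations:
        raise ValueError("corrupt archive: " + "; ".join(violations[:3]))
    muts = pd.read_csv(os.path.join(path, "mutations.tsv"), sep="\t")
    if len(muts):
        if data is not None:
            table = ats.assign_mutations(data)
            got = {(m.site, m.branch) for m in (table or [])}
            want = {(int(r["site"]), int(r["branch_child"]))
                    for _, r in muts.iterrows()}
            if got != want:
                raise ValueError("archived mutation table disagrees with data")
            ats.mutations = table
        else:
            ats.mutations = [MutationRecord(int(r["site"]),
                                            int(r["branch_child"]), frozenset())
                             for _, r in muts.iterrows()]
    return ats


# -- exports ----------------------------------------------------------------

def to_tree_sequence(ats: ATS):
    """Lossy export to a tskit tree sequence.

    Keeps nodes, ancestral-material edges, sites and mutations; trapped
    material, non-coalescing CA identity and recombination records have no
    tskit representation.  Single-tree ARGs round-trip exactly.
    """
    import tskit
    tables = tskit.TableCollection(sequence_length=ats.L)
    an = ats._require_valid()
    id_map = {}
    for u in sorted(ats.node_time):
        flags = tskit.NODE_IS_SAMPLE if ats.node_kind[u] == SAMPLE else 0
        id_map[u] = tables.nodes.add_row(flags=flags, time=ats.node_time[u])
    for u in sorted(an.mat):
        slot = an.parent_slot[u]
        for l, r, _ in an.mat[u]:
            if slot[0] == "ca":
                tables.edges.add_row(left=l, right=r, parent=id_map[slot[1]],
                                     child=id_map[u])
            else:
                rec = ats.recs[slot[1]]
                bnd = rec.breakpoint + 1
                if l < bnd:
                    tables.edges.add_row(left=l, right=min(r, bnd),
                                         parent=id_map[rec.left_parent],
                                         child=id_map[u])
                if r > bnd:
                    tables.edges.add_row(left=max(l, bnd), right=r,
                                         parent=id_map[rec.right_parent],
                                         child=id_map[u])
    for m in (ats.mutations or []):
        site_id = tables.sites.add_row(position=m.site, ancestral_state="0")
        tables.mutations.add_row(site=site_id, node=id_map[m.branch],
                                 derived_state="1")
    tables.sort()
    return tables.tree_sequence()


def write_tmrca_bed(tmrca, path, chrom: str = "sim") -> None:
    """Write a per-site TMRCA array as BED-like half-open intervals."""
    tmrca = np.asarray(tmrca)
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(tmrca) + 1):
            if i == len(tmrca) or tmrca[i] != tmrca[start]:
                fh.write(f"{chrom}\t{start}\t{i}\t{_F % tmrca[start]}\n")
                start = i
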