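"""Read/write genotype tables (STRUCTURE and GenePop dialects), filters, NEXUS.

STRUCTURE tables are tab-delimited; the first two columns are individual id and
population label, the rest are allele calls. Two layouts are supported:

* ``one-row``  — one row per individual, two adjacent columns per locus;
* ``two-rows`` — two consecutive rows per individual, one column per locus.

An optional first line of locus names is auto-detected. GenePop output uses
3-digit allele coding with ``000`` for missing genes.
"""

from __future__ import annotations

import io
import warnings

import numpy as np

from .dataset import MISSING, GenotypeDataset, LocusInfo


class GenotypeParseError(ValueError):
    """Raised on malformed genotype input, naming the offending row."""


def _tokenize(stream) -> list[list[str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = []
    for line in stream:
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        rows.append(line.split("\t"))
    return rows


def read_structure_table(
    stream,
    missing_code: int = MISSING,
    layout: str = "auto",
    motif_length: int = 2,
    locus_motifs: dict[str, int] | None = None,
) -> GenotypeDataset:
    """Parse a STRUCTURE-format tab-delimited genotype table.

    Parameters
    ----------
    stream : str or text file object
        Table contents. A leading row holding only locus names (no id/pop
        columns) is detected and used for locus ids.
    missing_code : int
        Integer code marking a missing gene in the input (default -9).
    layout : {"auto", "one-row", "two-rows"}
        ``one-row``: individual id, population, then two columns per locus.
        ``two-rows``: each individual spans two consecutive rows of one column
        per locus; ids and populations must match between the rows.
        ``auto`` chooses by checking for repeated consecutive ids.
    motif_length, locus_motifs
        Repeat-motif lengths in bp, either one value for all loci or a
        per-locus mapping (sizes in the table are fragment lengths in bp).

    Returns
    -------
    GenotypeDataset
        With per-locus ``allelic_range`` recomputed from the parsed calls.
    """
    rows = _tokenize(stream)
    if not rows:
        raise GenotypeParseError("empty stream: no genotype rows found")

    widths = {len(r) for r in rows}
    # A header row of locus names has fewer columns than data rows (no
    # id/population columns) or is fully non-numeric after column 2.
    locus_names: list[str] | None = None
    first = rows[0]

    def _is_int(tok: str) -> bool:
        try:
            int(tok)
            return True
        except ValueError:
            return False

    if len(rows) > 1 and not any(_is_int(t) for t in first):
        locus_names = [t for t in first if t.strip()]
        rows = rows[1:]
        widths = {len(r) for r in rows}

    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise GenotypeParseError(
            f"ragged rows: row {bad + 1} has {len(rows[bad])} columns, "
            f"expected {len(rows[0])}"
        )
    width = widths.pop()
    if width < 3:
        raise GenotypeParseError("rows must have id, population and allele columns")

    if layout == "auto":
        ids = [r[0] for r in rows]
        paired = len(rows) % 2 == 0 and all(
            ids[i] == ids[i + 1] for i in range(0, len(rows), 2)
        )
        # one-row tables repeat nothing consecutively (unique ids); an even
        # number of columns after id/pop also signals one-row.
        layout = "two-rows" if (paired and len(set(ids)) == len(rows) // 2) else "one-row"
    if layout not in ("one-row", "two-rows"):
        raise GenotypeParseError(f"unknown layout {layout!r}")

    if layout == "one-row":
        n_alleles = width - 2
        if n_alleles % 2:
            raise GenotypeParseError(
                "one-row layout needs an even number of allele columns"
            )
        n_loci = n_alleles // 2
        individuals, populations, calls = [], {}, []
        for ri, r in enumerate(rows):
            ind, pop = r[0].strip(), r[1].strip()
            if ind in populations:
                raise GenotypeParseError(f"duplicate individual id {ind!r} (row {ri + 1})")
            try:
                vals = np.array([int(t) for t in r[2:]], dtype=np.int64)
            except ValueError as e:
                raise GenotypeParseError(f"non-integer allele in row {ri + 1}: {e}")
            individuals.append(ind)
            populations[ind] = pop
            calls.append(vals.reshape(n_loci, 2))
        calls_arr = np.stack(calls)
    else:
        if len(rows) % 2:
            raise GenotypeParseError("two-rows layout needs an even number of rows")
        n_loci = width - 2
        individuals, populations, calls = [], {}, []
        for ri in range(0, len(rows), 2):
            r1, r2 = rows[ri], rows[ri + 1]
            if r1[0] != r2[0] or r1[1] != r2[1]:
                raise GenotypeParseError(
                    f"two-rows layout: rows {ri + 1}/{ri + 2} disagree on "
                    f"id/population ({r1[0]!r} vs {r2[0]!r})"
                )
            ind, pop = r1[0].strip(), r1[1].strip()
            if ind in populations:
                raise GenotypeParseError(
                    f"duplicate individual id {ind!r} (row {ri + 1})"
                )
            try:
                a = np.array([int(t) for t in r1[2:]], dtype=np.int64)
                b = np.array([int(t) for t in r2[2:]], dtype=np.int64)
            except ValueError as e:
                raise GenotypeParseError(f"non-integer allele near row {ri + 1}: {e}")
            individuals.append(ind)
            populations[ind] = pop
            calls.append(np.stack([a, b], axis=1))
        calls_arr = np.stack(calls)

    if locus_names is not None and len(locus_names) != n_loci:
        raise GenotypeParseError(
            f"header names {len(locus_names)} loci but rows carry {n_loci}"
        )
    names = locus_names or [f"L{i + 1}" for i in range(n_loci)]
    motifs = locus_motifs or {}
    loci = [LocusInfo(nm, motifs.get(nm, motif_length)) for nm in names]

    calls_arr[calls_arr == missing_code] = MISSING
    ds = GenotypeDataset(individuals, populations, loci, calls_arr)
    return ds.with_recomputed_ranges()


def write_structure(
    ds: GenotypeDataset,
    layout: str = "one-row",
    missing_code: int = MISSING,
    header: bool = True,
) -> str:
    """Serialize a dataset back to STRUCTURE tab-delimited text."""
    out = []
    if header:
        out.append("\t".join(ds.locus_ids))
    calls = ds.calls.copy()
    calls[calls == MISSING] = missing_code
    for i, ind in enumerate(ds.individuals):
        pop = ds.populations[ind]
        if layout == "one-row":
            out.append("\t".join([ind, pop] + [str(v) for v in calls[i].ravel()]))
        elif layout == "two-rows":
            out.append("\t".join([ind, pop] + [str(v) for v in calls[i, :, 0]]))
            out.append("\t".join([ind, pop] + [str(v) for v in calls[i, :, 1]]))
        else:
            raise ValueError(f"unknown layout {layout!r}")
    return "\n".join(out) + "\n"


def filter_individuals(ds: GenotypeDataset, min_typed_loci: int = 20) -> GenotypeDataset:
    """Retain individuals typed at >= ``min_typed_loci`` loci.

    The locus list is unchanged; per-locus allelic ranges are recomputed on
    the retained individuals.
    """
    if not 0 <= min_typed_loci <= ds.n_loci:
        raise ValueError(
            f"min_typed_loci must be in [0, {ds.n_loci}], got {min_typed_loci}"
        )
    keep = np.flatnonzero(ds.typed_locus_counts() >= min_typed_loci)
    if keep.size == 0:
        warnings.warn("filter_individuals removed every individual")
    return ds.take_individuals(keep).with_recomputed_ranges()


def exclude_loci(ds: GenotypeDataset, locus_ids: list[str]) -> GenotypeDataset:
    """Drop the named loci from the dataset (individuals unchanged)."""
    known = set(ds.locus_ids)
    unknown = [l for l in locus_ids if l not in known]
    if unknown:
        raise ValueError(f"unknown locus ids: {unknown}")
    drop = set(locus_ids)
    keep = np.array([i for i, l in enumerate(ds.locus_ids) if l not in drop], dtype=np.intp)
    return ds.take_loci(keep)


def largest_range_loci(ds: GenotypeDataset, n: int = 4) -> list[str]:
    """Ids of the ``n`` loci with the largest allelic ranges (ties by order).

    Used to build the default exclusion list for ABC, mirroring the removal of
    loci whose wide allelic ranges distort the simulated-statistic cloud.
    """
    ranges = np.array([loc.allelic_range for loc in ds.loci])
    order = np.argsort(-ranges, kind="stable")[:n]
    return [ds.loci[i].id for i in sorted(order)]


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def write_genepop(ds: GenotypeDataset, title: str = "wintermoth-abc export") -> str:
    """Serialize to GenePop v4 text with 3-digit allele coding.

    Missing genes are written ``000``. Raises if any allele size needs more
    than three digits.
    """
    if (ds.calls[ds.typed_mask()] > 999).any():
        raise ValueError("allele size needs >3 digits; recode sizes before export")
    lines = [title]
    lines.extend(ds.locus_ids)
    pops = ds.population_indices()
    for pop, idx in pops.items():
        lines.append("POP")
        for i in idx:
            genos = []
            for l in range(ds.n_loci):
                a, b = ds.calls[i, l]
                if a == MISSING:
                    genos.append("000000")
                else:
                    genos.append(f"{a:03d}{b:03d}")
            lines.append(f"{ds.individuals[i]} ,  " + " ".join(genos))
    return "\n".join(lines) + "\n"


def read_genepop(stream, motif_length: int = 2) -> GenotypeDataset:
    """Parse GenePop v4 text (3-digit coding) back into a dataset."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if len(lines) < 3:
        raise GenotypeParseError("truncated GenePop input")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        # locus names may be one per line or comma-separated
        loci.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    individuals, populations, calls = [], {}, []
    pop_no = 0
    while i < len(body):
        if body[i].strip().upper() == "POP":
            pop_no += 1
            i += 1
            continue
        name, _, genos = body[i].partition(",")
        toks = genos.split()
        if len(toks) != len(loci):
            raise GenotypeParseError(f"row {i}: expected {len(loci)} genotypes")
        row = np.empty((len(loci), 2), dtype=np.int64)
        for l, t in enumerate(toks):
            if len(t) != 6:
                raise GenotypeParseError(f"row {i}: genotype {t!r} not 6 digits")
            a, b = int(t[:3]), int(t[3:])
            row[l] = (MISSING, MISSING) if a == 0 or b == 0 else (a, b)
        ind = name.strip()
        individuals.append(ind)
        populations[ind] = f"pop{pop_no}"
        calls.append(row)
        i += 1
    ds = GenotypeDataset(
        individuals,
        populations,
        [LocusInfo(l, motif_length) for l in loci],
        np.stack(calls),
    )
    return ds.with_recomputed_ranges()


# ---------------------------------------------------------------------------
# NEXUS distances
# ---------------------------------------------------------------------------


def write_nexus_distances(labels: list[str], matrix: np.ndarray) -> str:
    """Write a symmetric distance matrix as a NEXUS DISTANCES block.

    The output loads in SplitsTree for NeighborNet construction (the network
    algorithm itself is outside this package).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} labels")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    safe = [lbl.replace(" ", "_") for lbl in labels]
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={n};",
        "  TAXLABELS " + " ".join(safe) + ";",
        "END;",
        "",
        "BEGIN DISTANCES;",
        f"  DIMENSIONS NTAX={n};",
        "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
        "  MATRIX",
    ]
    for lbl, row in zip(safe, matrix):
        lines.append("    " + lbl + " " + " ".join(f"{v:.6f}" for v in row))
    lines += ["  ;", "END;", ""]
    return "\n".join(lines)
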