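"""File formats: bedGraph tracks, contact matrices, manifests.

Tracks travel as bedGraph (0-based, half-open, tab-separated: chrom, start,
end, value; masked bins are simply absent). Contact matrices travel either
as coordinate-list text (``chrom  bin_i  bin_j  count`` with a small header
of ``#key=value`` lines) or as dense ``.npy`` binaries; a read-only adapter
for single-resolution cooler HDF5 files is provided behind this boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .genome import BinnedTrack, GenomeSpec
from .hic_core import ContactMatrix

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "write_matrix_txt",
    "read_matrix_txt",
    "write_matrix_npy",
    "read_matrix_npy",
    "write_manifest",
    "read_manifest",
    "read_cool",
]


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write unmasked bins as bedGraph lines (masked bins are omitted)."""
    bs = track.genome.bin_size
    with open(path, "w") as fh:
        for name in track.genome.names:
            vals, mask = track.chrom_view(name)
            for i in np.nonzero(~mask)[0]:
                fh.write(f"{name}\t{i * bs}\t{(i + 1) * bs}\t{vals[i]:.6g}\n")


def read_bedgraph(
    path: str | Path, genome: GenomeSpec | None = None, name: str = ""
) -> BinnedTrack:
    """Read a bedGraph into a BinnedTrack.

    Without an explicit genome, chromosome extents and the bin size are
    inferred from the records (constant interval width required); intervals
    absent from the file are masked.
    """
    chroms: list[str] = []
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")[:4]
            if c not in chroms:
                chroms.append(c)
            rows.append((c, int(s), int(e), float(v)))
    if not rows:
        raise ValueError(f"no records in {path}")
    if genome is None:
        widths = {e - s for _, s, e, _ in rows}
        if len(widths) != 1:
            raise ValueError("cannot infer bin size: interval widths vary")
        bs = widths.pop()
        ends = {c: 0 for c in chroms}
        for c, _, e, _ in rows:
            ends[c] = max(ends[c], e)
        genome = GenomeSpec(tuple((c, ends[c] // bs) for c in chroms), bs)
    bs = genome.bin_size
    vals = np.full(genome.n_bins, np.nan)
    slices = genome.chrom_slices()
    for c, s, e, v in rows:
        if c not in slices:
            raise ValueError(f"chromosome {c!r} not in the supplied genome")
        if s % bs or e - s != bs:
            raise ValueError(f"interval {c}:{s}-{e} does not match bin size {bs}")
        vals[slices[c].start + s // bs] = v
    return BinnedTrack(genome, vals, name=name)


def write_matrix_txt(matrix: ContactMatrix, path: str | Path) -> None:
    """Coordinate-list text: upper-triangle non-zero finite entries."""
    with open(path, "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\n#n_bins={matrix.n_bins}\n")
        fh.write(f"#bin_size={matrix.bin_size}\n#scale={matrix.scale}\n")
        data = matrix.masked_data()
        iu, ju = np.triu_indices(matrix.n_bins)
        vals = data[iu, ju]
        keep = np.isfinite(vals) & (vals != 0)
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            fh.write(f"{matrix.chrom}\t{i}\t{j}\t{v:.8g}\n")


def read_matrix_txt(path: str | Path) -> ContactMatrix:
    header: dict[str, str] = {}
    entries: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                header[k] = v
                continue
            if not line:
                continue
            _, i, j, v = line.split("\t")[:4]
            entries.append((int(i), int(j), float(v)))
    n = int(header["n_bins"])
    data = np.zeros((n, n))
    for i, j, v in entries:
        data[i, j] = v
        data[j, i] = v
    scale = header.get("scale", "raw")
    valid = np.ones(n, bool)
    if scale != "raw":  # bins with no recorded signal were masked upstream
        valid = data.any(axis=0)
        data[~valid, :] = np.nan
        data[:, ~valid] = np.nan
    return ContactMatrix(header["chrom"], int(header["bin_size"]), data, valid, scale)


def write_matrix_npy(matrix: ContactMatrix, path: str | Path) -> None:
    """Dense binary option: the NaN-masked matrix as a .npy array."""
    np.save(path, matrix.masked_data())


def read_matrix_npy(
    path: str | Path, chrom: str, bin_size: int, scale: str = "raw"
) -> ContactMatrix:
    data = np.load(path)
    valid = ~np.all(~np.isfinite(data) | (data == 0), axis=0)
    data = np.where(np.isfinite(data), data, np.nan)
    return ContactMatrix(chrom, bin_size, data, valid, scale)


def write_manifest(params: dict, path: str | Path) -> None:
    """Record generator/analysis parameters and seeds as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_cool(path: str | Path, chrom: str) -> ContactMatrix:
    """Read one chromosome's cis matrix from a single-resolution cooler file.

    Minimal adapter over the cooler HDF5 layout (groups ``chroms``, ``bins``,
    ``pixels``, ``indexes``): returns raw counts with all bins valid unless a
    ``bins/weight`` column marks them otherwise.
    """
    import h5py

    with h5py.File(path, "r") as h5:
        names = [
            n.decode() if isinstance(n, bytes) else str(n) for n in h5["chroms/name"][:]
        ]
        if chrom not in names:
            raise KeyError(f"chromosome {chrom!r} not in {path}")
        cid = names.index(chrom)
        bin_chrom = h5["bins/chrom"][:]
        sel = np.nonzero(bin_chrom == cid)[0]
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        starts = h5["bins/start"][lo : lo + 2]
        bin_size = int(starts[1] - starts[0]) if len(starts) > 1 else int(
            h5["bins/end"][lo] - h5["bins/start"][lo]
        )
        offsets = h5["indexes/bin1_offset"][:]
        p0, p1 = int(offsets[lo]), int(offsets[hi])
        b1 = h5["pixels/bin1_id"][p0:p1]
        b2 = h5["pixels/bin2_id"][p0:p1]
        cnt = h5["pixels/count"][p0:p1].astype(float)
        cis = b2 < hi
        n = hi - lo
        data = np.zeros((n, n))
        i, j = b1[cis] - lo, b2[cis] - lo
        data[i, j] = cnt[cis]
        data[j, i] = cnt[cis]
        valid = np.ones(n, bool)
        if "weight" in h5["bins"]:
            w = h5["bins/weight"][lo:hi]
            valid = np.isfinite(w)
    return ContactMatrix(chrom, bin_size, data, valid, "raw")
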