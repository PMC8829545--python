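"""Reading/writing event data, panel configuration and cohort manifests.

Event files are either FCS 3.0/3.1 (read) / FCS 3.1 (write) or
tab-separated text with a header row of marker names, one cell per row.
Raw intensities are variance-stabilized with the standard cytometry
arcsinh transform ``asinh(x / cofactor)``; the cofactor defaults to 5,
the mass-cytometry convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._fcs import read_fcs, write_fcs
from .events import EventTable

__all__ = [
    "PanelConfig",
    "CohortManifest",
    "read_events",
    "write_events",
    "arcsinh_transform",
    "downsample_events",
    "load_panel",
    "load_manifest",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0


@dataclass
class PanelConfig:
    """Antibody panel: marker order plus clustering/gating channel subsets."""

    markers: list[str]
    clustering_markers: list[str] = field(default_factory=list)
    gating_markers: list[str] = field(default_factory=list)
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        unknown = [m for m in self.clustering_markers if m not in self.markers]
        if unknown:
            raise ValueError(f"clustering_markers not in panel: {unknown}")
        unknown = [m for m in self.gating_markers if m not in self.markers]
        if unknown:
            raise ValueError(f"gating_markers not in panel: {unknown}")
        if not self.clustering_markers:
            self.clustering_markers = list(self.markers)

    def clustering_matrix(self, table: EventTable) -> np.ndarray:
        """Cells x clustering-marker feature matrix."""
        idx = [table.marker_index(m) for m in self.clustering_markers]
        return table.values[:, idx]


@dataclass
class CohortManifest:
    """One row per event file: path, subject, group, compartment."""

    entries: pd.DataFrame  # columns: path, subject_id, group, compartment

    def __post_init__(self) -> None:
        required = {"path", "subject_id", "group", "compartment"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest is missing columns: {sorted(missing)}")
        dup = self.entries.duplicated(subset=["subject_id", "compartment"])
        if dup.any():
            pairs = self.entries.loc[dup, ["subject_id", "compartment"]]
            raise ValueError(
                f"duplicate (subject_id, compartment) pairs in manifest: "
                f"{pairs.to_records(index=False).tolist()}"
            )


# ---------------------------------------------------------------------------
# event file I/O


def _read_raw(path: Path) -> tuple[np.ndarray, list[str]]:
    with open(path, "rb") as fh:
        magic = fh.read(6)
    if magic.startswith(b"FCS3"):
        data, names, _kw = read_fcs(path)
        return data, names
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.to_numpy(dtype=float), list(df.columns)


def read_events(
    path: str | Path,
    panel: PanelConfig,
    subject_id: str = "unknown",
    group: str = "unknown",
    compartment: str = "blood",
) -> EventTable:
    """Read one event file and reorder its channels to panel order.

    Channels not in the panel are dropped with a warning; a panel marker
    absent from the file is an error naming the missing marker(s).
    """
    path = Path(path)
    data, names = _read_raw(path)
    missing = [m for m in panel.markers if m not in names]
    if missing:
        raise ValueError(f"{path}: required markers missing from file: {missing}")
    extra = [c for c in names if c not in panel.markers]
    if extra:
        logger.warning("%s: dropping channels not in panel: %s", path, extra)
    order = [names.index(m) for m in panel.markers]
    n = data.shape[0]
    return EventTable(
        values=data[:, order],
        markers=list(panel.markers),
        subject_id=np.full(n, subject_id, dtype=object),
        group=np.full(n, group, dtype=object),
        compartment=np.full(n, compartment, dtype=object),
    )


def write_events(path: str | Path, table: EventTable, format: str | None = None) -> None:
    """Write the marker matrix of one table as FCS 3.1 or TSV.

    Format is taken from the file suffix (``.fcs`` / anything else =
    TSV) unless given explicitly.
    """
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "tsv")
    if fmt == "fcs":
        write_fcs(path, table.values, table.markers)
    elif fmt == "tsv":
        pd.DataFrame(table.values, columns=table.markers).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# transforms


def arcsinh_transform(table: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Apply ``asinh(x / cofactor)`` to every intensity.

    Monotone per marker, so gating order relations are preserved.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = table.take(np.arange(table.n_cells))
    out.values = np.arcsinh(table.values / cofactor)
    return out


def downsample_events(table: EventTable, n_max: int, seed: int = 0,
                      stratify_by_subject: bool = False) -> EventTable:
    """Uniform random subset of at most ``n_max`` cells, without replacement.

    Tables at or under the cap are returned unchanged. The optional
    stratified mode draws proportionally within each subject. Retained
    cells keep their original order.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n = table.n_cells
    if n <= n_max:
        return table
    rng = np.random.default_rng(seed)
    if not stratify_by_subject:
        keep = np.sort(rng.choice(n, size=n_max, replace=False))
    else:
        parts = []
        subjects = table.subjects
        # proportional allocation, largest-remainder rounding
        sizes = np.array([(table.subject_id == s).sum() for s in subjects])
        quota = n_max * sizes / n
        counts = np.floor(quota).astype(int)
        rem = n_max - counts.sum()
        order = np.argsort(-(quota - counts))
        counts[order[:rem]] += 1
        for s, c in zip(subjects, counts):
            idx = np.flatnonzero(table.subject_id == s)
            parts.append(rng.choice(idx, size=min(c, len(idx)), replace=False))
        keep = np.sort(np.concatenate(parts))
    return table.take(keep)


# ---------------------------------------------------------------------------
# config files


def load_panel(path: str | Path) -> PanelConfig:
    """Panel config from YAML: markers, clustering/gating subsets, cofactor."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    markers = list(cfg["markers"])

    def subset(key):
        value = cfg.get(key, [])
        if isinstance(value, Mapping) and "exclude" in value:
            excl = set(value["exclude"])
            return [m for m in markers if m not in excl]
        return list(value)

    return PanelConfig(
        markers=markers,
        clustering_markers=subset("clustering_markers"),
        gating_markers=subset("gating_markers"),
        cofactor=float(cfg.get("cofactor", DEFAULT_COFACTOR)),
    )


def load_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return CohortManifest(entries=df)


def read_cohort(manifest: CohortManifest, panel: PanelConfig,
                base_dir: str | Path | None = None) -> EventTable:
    """Read and stack every file of a cohort manifest."""
    from .events import concat_tables

    tables = []
    for row in manifest.entries.itertuples(index=False):
        p = Path(row.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        tables.append(
            read_events(p, panel, subject_id=row.subject_id,
                        group=row.group, compartment=row.compartment)
        )
    return concat_tables(tables)


def write_cohort(table: EventTable, out_dir: str | Path, format: str = "tsv") -> Path:
    """Write one file per subject x compartment plus manifest and truth sidecar.

    Returns the manifest path. Truth labels (synthetic cohorts) go to
    ``truth.tsv`` keyed by file and within-file cell index.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fcs" if format == "fcs" else ".tsv"
    rows = []
    truth_rows = []
    for subject in table.subjects:
        mask_s = table.subject_id == subject
        group = table.group[mask_s][0]
        for comp in pd.unique(table.compartment[mask_s]):
            idx = np.flatnonzero(mask_s & (table.compartment == comp))
            sub = table.take(idx)
            fname = f"{subject}_{comp}{suffix}"
            write_events(out_dir / fname, sub, format=format)
            rows.append({"path": fname, "subject_id": subject,
                         "group": group, "compartment": comp})
            if sub.truth_population is not None:
                truth_rows.append(pd.DataFrame({
                    "path": fname,
                    "cell_index": np.arange(sub.n_cells),
                    "truth_population": sub.truth_population,
                }))
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    if truth_rows:
        pd.concat(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest_path


def load_cohort_spec(path: str | Path):
    """Build a :class:`~cytopheno.synthetic.CohortSpec` from a YAML file.

    Nested layout: ``markers``, ``populations`` (name, mean, sd — scalars
    broadcast over the panel — or per-marker maps, base_logit), ``groups``,
    ``subjects_per_group``, ``cells_per_subject``, ``subject_sd``,
    ``enrichment``/``compartment_shift`` as ``group:population: value``
    maps, ``compartments``, ``seed``.
    """
    from .synthetic import CohortSpec, PopulationArchetype

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    markers = list(cfg["markers"])
    p = len(markers)

    def vector(value, default):
        if value is None:
            value = default
        if isinstance(value, Mapping):
            base = np.full(p, float(value.get("default", default)))
            for m, v in value.items():
                if m == "default":
                    continue
                base[markers.index(m)] = float(v)
            return base
        if isinstance(value, Sequence) and not isinstance(value, str):
            return np.asarray(value, dtype=float)
        return np.full(p, float(value))

    pops = [
        PopulationArchetype(
            name=pc["name"],
            mean_vector=vector(pc.get("mean"), 0.0),
            sd_vector=vector(pc.get("sd"), 0.3),
            base_logit=float(pc.get("base_logit", 0.0)),
        )
        for pc in cfg["populations"]
    ]

    def pair_map(section):
        out = {}
        for outer, inner in (cfg.get(section) or {}).items():
            for pop, v in inner.items():
                out[(outer, pop)] = float(v)
        return out

    spg = cfg.get("subjects_per_group", 5)
    return CohortSpec(
        populations=pops,
        markers=markers,
        groups=tuple(cfg.get("groups", ("controller", "acute", "chronic"))),
        subjects_per_group=spg if isinstance(spg, (int, Mapping)) else int(spg),
        cells_per_subject=int(cfg.get("cells_per_subject", 2000)),
        subject_sd=float(cfg.get("subject_sd", 0.0)),
        enrichment=pair_map("enrichment"),
        enrichable=cfg.get("enrichable"),
        compartments=tuple(cfg.get("compartments", ("blood",))),
        compartment_shift=pair_map("compartment_shift"),
        seed=int(cfg.get("seed", 0)),
    )
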