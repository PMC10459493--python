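"""Docking-engine configuration, scored-pose parsing, ranking and convergence.

This module speaks the rDock/CmDock file dialects — the plain-text ``.prm``
parameter file with an ``RbtLigandSiteMapper`` cavity-mapping section, and SD
files whose per-record tags carry the total and intermolecular (INTER) score
components — without reimplementing the engine.  Scores follow the rDock
convention: lower is better.  A deterministic surrogate scorer built on the
interaction-fingerprint module allows the whole pipeline to run engine-free.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigurationError, ParseError

DEFAULT_SCORE_TAG = "SCORE"
DEFAULT_INTER_TAG = "SCORE.INTER"


@dataclass
class CavityConfig:
    """rDock/CmDock ligand-site-mapper cavity definition.

    Defaults reproduce the published Fc-region docking setup: a 4 Angstrom
    grid around the reference ligand's heavy atoms with receptor flexibility
    for terminal OH/NH3+ groups within 3 Angstrom of the site.
    """

    reference_ligand: str
    radius: float = 4.0
    small_sphere: float = 1.0
    min_volume: float = 100.0
    max_cavities: int = 1
    vol_incr: float = 0.0
    gridstep: float = 0.5
    receptor_flex: float = 3.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError(f"radius must be > 0, got {self.radius}")
        if self.gridstep <= 0:
            raise ConfigurationError(f"gridstep must be > 0, got {self.gridstep}")
        if self.max_cavities < 1:
            raise ConfigurationError(
                f"max_cavities must be >= 1, got {self.max_cavities}"
            )


@dataclass
class ScoreRecord:
    """One scored docking pose."""

    peptide_id: str
    score: float
    inter_score: float | None = None
    run_index: int | None = None
    record_index: int | None = None
    rejected: bool = False

    def key(self, which: str = "total") -> float:
        if which == "inter":
            if self.inter_score is None:
                raise ValueError(f"record {self.peptide_id} has no inter score")
            return self.inter_score
        return self.score


@dataclass
class RankedList:
    """Best-first per-peptide ranking (one best pose per peptide)."""

    records: list[ScoreRecord]
    n: int
    key: str = "total"

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.peptide_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.records) + 1),
                "sequence": [r.peptide_id for r in self.records],
                "score": [r.score for r in self.records],
                "inter_score": [r.inter_score for r in self.records],
            }
        )


def write_prm_config(
    path: str | Path,
    receptor_file: str | Path,
    cavity: CavityConfig,
    runs: int = 100,
    title: str = "peplib docking configuration",
    check_reference_exists: bool = True,
) -> dict:
    """Write an rDock/CmDock ``.prm`` parameter file; returns the run manifest.

    The mapper section uses ``RbtLigandSiteMapper`` with the cavity keys
    (RADIUS, SMALL_SPHERE, MIN_VOLUME, MAX_CAVITIES, VOL_INCR, GRIDSTEP) and
    the receptor-flexibility key at the top level.  ``runs`` is the engine's
    ``-n`` sampling parameter, recorded in the returned manifest.
    """
    if runs < 1:
        raise ConfigurationError(f"runs must be >= 1, got {runs}")
    if check_reference_exists and not Path(cavity.reference_ligand).exists():
        raise ConfigurationError(
            f"reference ligand file not found: {cavity.reference_ligand}"
        )
    lines = [
        "RBT_PARAMETER_FILE_V1.00",
        f"TITLE {title}",
        "",
        f"RECEPTOR_FILE {receptor_file}",
        f"RECEPTOR_FLEX {cavity.receptor_flex}",
        "",
        "SECTION MAPPER",
        "    SITE_MAPPER RbtLigandSiteMapper",
        f"    REF_MOL {cavity.reference_ligand}",
        f"    RADIUS {cavity.radius}",
        f"    SMALL_SPHERE {cavity.small_sphere}",
        f"    MIN_VOLUME {cavity.min_volume}",
        f"    MAX_CAVITIES {cavity.max_cavities}",
        f"    VOL_INCR {cavity.vol_incr}",
        f"    GRIDSTEP {cavity.gridstep}",
        "END_SECTION",
        "",
        "SECTION CAVITY",
        "    SCORING_FUNCTION RbtCavityGridSF",
        "    WEIGHT 1.0",
        "END_SECTION",
        "",
    ]
    Path(path).write_text("\n".join(lines))
    return {
        "prm_file": str(path),
        "receptor_file": str(receptor_file),
        "runs": runs,
        "cavity": {k: getattr(cavity, k) for k in (
            "reference_ligand", "radius", "small_sphere", "min_volume",
            "max_cavities", "vol_incr", "gridstep", "receptor_flex")},
    }


def parse_prm(path: str | Path) -> dict:
    """Round-trip parser for the prm dialect: top-level keys plus sections."""
    result: dict = {"_sections": {}}
    current: dict | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "RBT_PARAMETER_FILE_V1.00":
            result["_format"] = line
            continue
        if line.startswith("SECTION"):
            name = line.split(None, 1)[1]
            current = {}
            result["_sections"][name] = current
            continue
        if line == "END_SECTION":
            current = None
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: cannot parse {raw!r}")
        key, value = parts
        (current if current is not None else result)[key] = value
    return result


def parse_scored_sd(
    path: str | Path,
    score_tag: str = DEFAULT_SCORE_TAG,
    inter_tag: str = DEFAULT_INTER_TAG,
    run_tag: str = "RUN",
) -> list[ScoreRecord]:
    """Parse an engine-output SD file into :class:`ScoreRecord` objects.

    The peptide id is the SD title (``_Name``).  A record missing the INTER
    tag is kept with the total score only and triggers a warning; a
    non-numeric score tag raises :class:`ParseError` with the record index.
    Records without an explicit run tag are numbered by order of appearance
    within their peptide id.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records: list[ScoreRecord] = []
    seen: dict[str, int] = {}
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError("malformed SD block", record_index=i)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
        if not mol.HasProp(score_tag):
            raise ParseError(f"missing score tag {score_tag!r}", record_index=i)
        try:
            score = float(mol.GetProp(score_tag))
        except ValueError:
            raise ParseError(
                f"non-numeric {score_tag!r} value {mol.GetProp(score_tag)!r}",
                record_index=i,
            ) from None
        inter: float | None = None
        if mol.HasProp(inter_tag):
            try:
                inter = float(mol.GetProp(inter_tag))
            except ValueError:
                raise ParseError(
                    f"non-numeric {inter_tag!r} value {mol.GetProp(inter_tag)!r}",
                    record_index=i,
                ) from None
        else:
            warnings.warn(
                f"record {i} ({name}): no {inter_tag!r} tag; keeping total only",
                stacklevel=2,
            )
        if mol.HasProp(run_tag):
            try:
                run = int(float(mol.GetProp(run_tag)))
            except ValueError:
                raise ParseError(
                    f"non-numeric {run_tag!r} value", record_index=i
                ) from None
        else:
            run = seen.get(name, 0) + 1
        seen[name] = run
        records.append(
            ScoreRecord(
                peptide_id=name, score=score, inter_score=inter,
                run_index=run, record_index=i,
            )
        )
    return records


def rank_and_select(
    records: Iterable[ScoreRecord], n: int, key: str = "total"
) -> RankedList:
    """Select the top ``n`` peptides by best (minimum) pose score.

    Per peptide, the best pose across runs is taken; peptides are then sorted
    ascending by that score with lexicographic sequence order breaking ties.
    ``n`` exceeding the number of distinct peptides returns all with a warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    best: dict[str, ScoreRecord] = {}
    for rec in records:
        if rec.rejected:
            continue
        cur = best.get(rec.peptide_id)
        if cur is None or rec.key(key) < cur.key(key):
            best[rec.peptide_id] = rec
    if not best:
        raise ValueError("no usable score records")
    ordered = sorted(best.values(), key=lambda r: (r.key(key), r.peptide_id))
    if n > len(ordered):
        warnings.warn(
            f"requested top {n} but only {len(ordered)} distinct peptides",
            stacklevel=2,
        )
        n = len(ordered)
    return RankedList(records=ordered[:n], n=n, key=key)


def score_convergence(
    records: Iterable[ScoreRecord],
    run_budgets: Sequence[int] | None = None,
    sample_fraction: float = 1.0,
    seed: int = 0,
    key: str = "inter",
) -> pd.DataFrame:
    """Mean best score versus run budget over a random peptide sample.

    For each budget ``r`` the best (minimum) score within the first ``r`` runs
    is taken per sampled peptide and averaged.  The curve is monotone
    non-increasing in ``r`` for every peptide, hence also in the mean.
    Sampling ``sample_fraction`` of the distinct peptide ids is reproducible
    under ``seed``.
    """
    if not 0.0 < sample_fraction <= 1.0:
        raise ValueError(f"sample_fraction must be in (0, 1], got {sample_fraction}")
    by_id: dict[str, list[ScoreRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.peptide_id, []).append(rec)
    ids = sorted(by_id)
    if not ids:
        raise ValueError("no score records")
    if sample_fraction < 1.0:
        k = max(1, int(round(sample_fraction * len(ids))))
        rng = np.random.default_rng(seed)
        ids = sorted(rng.choice(ids, size=k, replace=False))
    series = {}
    max_runs = 0
    for pid in ids:
        runs = sorted(by_id[pid], key=lambda r: r.run_index or 0)
        scores = np.array([r.key(key) for r in runs], dtype=float)
        series[pid] = np.minimum.accumulate(scores)
        max_runs = max(max_runs, len(scores))
    if run_budgets is None:
        run_budgets = list(range(1, max_runs + 1))
    rows = []
    for r in run_budgets:
        if r < 1:
            raise ValueError(f"run budget must be >= 1, got {r}")
        vals = [s[min(r, len(s)) - 1] for s in series.values()]
        rows.append({"run_count": r, "mean_best_score": float(np.mean(vals)),
                     "n_sampled": len(vals)})
    return pd.DataFrame(rows)


DEFAULT_SURROGATE_WEIGHTS: Mapping[str, float] = {
    "hbond_donor_to_ligand": 1.0,
    "hbond_acceptor_from_ligand": 1.0,
    "hydrophobic": 0.5,
    "pi_pi": 1.5,
    "cation_pi": 1.0,
    "salt_bridge": 2.0,
}


def surrogate_score(
    pose,
    receptor,
    criteria=None,
    peptide_id: str | None = None,
    run_index: int | None = None,
    cavity_center: np.ndarray | None = None,
    cavity_radius: float | None = None,
    weights: Mapping[str, float] | None = None,
) -> ScoreRecord:
    """Deterministic engine-free pose score for pipeline testing.

    The score is minus the weighted count of geometric interactions detected
    by the fingerprint module (lower = better, zero interactions = 0).  This
    is NOT the rDock SF3 scoring function — it exists so the pipeline can run
    and be tested without a docking engine.  Poses whose centroid lies outside
    the optional spherical cavity bound are returned with ``rejected=True``
    and no score computed.
    """
    from .fingerprints import detect_interactions

    weights = weights or DEFAULT_SURROGATE_WEIGHTS
    if peptide_id is None:
        peptide_id = pose.GetProp("_Name") if pose.HasProp("_Name") else "pose"
    if cavity_center is not None and cavity_radius is not None:
        centroid = pose.GetConformer().GetPositions().mean(axis=0)
        if np.linalg.norm(centroid - np.asarray(cavity_center)) > cavity_radius:
            return ScoreRecord(
                peptide_id=peptide_id, score=float("nan"), inter_score=None,
                run_index=run_index, rejected=True,
            )
    fp = detect_interactions(receptor, pose, criteria=criteria)
    total = -sum(weights.get(t, 0.0) * c for (_res, t), c in fp.counts.items())
    return ScoreRecord(
        peptide_id=peptide_id, score=float(total), inter_score=float(total),
        run_index=run_index,
    )
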