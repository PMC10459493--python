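"""End-to-end orchestration: enumerate -> profile -> dock-prep -> score ->
fingerprint -> cluster -> enrich, with a hash-recorded run manifest.

The pipeline is deterministic under a fixed :class:`RunConfig` seed when the
surrogate scorer is used, so re-running an identical config reproduces
identical outputs.  Defaults follow the published screen where one exists:
length-4 peptides over the 20-letter alphabet, ionization at pH 7.4 and
charge profiling at pH 7, a 4 Angstrom cavity radius, 100 docking runs,
top-100 and top-10 selections, clustering threshold 0.6 with singleton
outliers, and rest-group pooling below two occurrences.  Desk-scale test runs
override the alphabet/length only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import docking, enrichment, fixtures, library, properties
from .clustering import cluster_fingerprints, cluster_report
from .errors import PeplibError
from .fingerprints import GeometricCriteria, InteractionFingerprinter

logger = logging.getLogger("peplib.pipeline")

STAGES = ("enumerate", "profile", "dock_prep", "score", "fingerprint",
          "cluster", "enrich")


@dataclass
class RunConfig:
    """Serializable pipeline configuration; defaults match the published run."""

    alphabet: str = library.CANONICAL_ALPHABET
    length: int = 4
    ph_ionize: float = 7.4
    ph_charge: float = 7.0
    pka_table: str = "lehninger"
    radius: float = 4.0
    small_sphere: float = 1.0
    min_volume: float = 100.0
    max_cavities: int = 1
    vol_incr: float = 0.0
    gridstep: float = 0.5
    receptor_flex: float = 3.0
    runs: int = 100
    top_n: int = 100
    top_n_small: int = 10
    cluster_threshold: float = 0.6
    cluster_min_size: int = 2
    min_count: int = 2
    noise_sd: float = 0.5
    seed: int = 42
    outdir: str = "peplib_run"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config (JSON or ``key = value`` text)."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        defaults = cls()
        kwargs = {}
        for key, value in data.items():
            if not hasattr(defaults, key):
                raise PeplibError(f"unknown config key {key!r}")
            target = type(getattr(defaults, key))
            kwargs[key] = target(value)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all pipeline stages on synthetic fixtures; return the manifest.

    Every stage writes its outputs under ``config.outdir`` and the manifest
    records stage order, timing, parameters and the SHA-256 of every output
    file.  A stage failure aborts with the stage name while preserving the
    outputs of completed stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.to_json()),
        "stages": [],
        "outputs": {},
    }
    rng_seed = int(config.seed) % (2 ** 31)

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - t0, 3), **info}
        )
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    def register(name: str, path: Path) -> Path:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }
        return path

    stage = "enumerate"
    try:
        t0 = time.time()
        lib = library.enumerate_library(config.alphabet, config.length)
        lib_path = outdir / "library.fasta"
        n = library.write_sequences(lib, lib_path, fmt="fasta")
        register("library", lib_path)
        record(stage, t0, n_sequences=n)

        stage = "profile"
        t0 = time.time()
        records = list(
            properties.iter_descriptor_records(lib, ph=config.ph_charge)
        )
        props_path = outdir / "properties.csv"
        properties.write_property_csv(records, props_path)
        summary = properties.library_profile(records)
        summary_path = outdir / "profile_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        register("properties", props_path)
        register("profile_summary", summary_path)
        record(stage, t0, n_records=len(records))

        stage = "dock_prep"
        t0 = time.time()
        receptor_path = outdir / "receptor.pdb"
        receptor = fixtures.make_toy_receptor(receptor_path)
        ref_path = outdir / "reference_ligand.sdf"
        ref_poses, _ = fixtures.make_poses_with_planted_interactions(
            receptor, [[("pi_pi", "A:HIS435")]], path=ref_path,
            pose_ids=["reference"],
        )
        cavity = docking.CavityConfig(
            reference_ligand=str(ref_path), radius=config.radius,
            small_sphere=config.small_sphere, min_volume=config.min_volume,
            max_cavities=config.max_cavities, vol_incr=config.vol_incr,
            gridstep=config.gridstep, receptor_flex=config.receptor_flex,
        )
        prm_path = outdir / "dock.prm"
        prm_manifest = docking.write_prm_config(
            prm_path, receptor_path, cavity, runs=config.runs
        )
        register("prm", prm_path)
        register("receptor", receptor_path)
        register("reference_ligand", ref_path)
        record(stage, t0, **{"runs": prm_manifest["runs"]})

        stage = "score"
        t0 = time.time()
        sequences = list(lib)
        criteria = GeometricCriteria()
        plants = _synthetic_plants(receptor, sequences, rng_seed)
        poses_path = outdir / "poses.sdf"
        poses, _truth = fixtures.make_poses_with_planted_interactions(
            receptor, plants, path=poses_path, pose_ids=sequences
        )
        base_scores = {
            seq: docking.surrogate_score(
                pose, receptor, criteria=criteria, peptide_id=seq
            ).score
            for seq, pose in zip(sequences, poses)
        }
        scored_path = outdir / "scored.sdf"
        fixtures.make_scored_sd(
            scored_path, base_scores, runs=config.runs,
            noise_sd=config.noise_sd, seed=rng_seed,
        )
        score_records = docking.parse_scored_sd(scored_path)
        ranked = docking.rank_and_select(
            score_records, min(config.top_n, len(sequences))
        )
        top_small = docking.rank_and_select(
            score_records, min(config.top_n_small, len(sequences))
        )
        ranked_path = outdir / "top_ranked.csv"
        ranked.to_frame().to_csv(ranked_path, index=False)
        top_small_path = outdir / "top_small.csv"
        top_small.to_frame().to_csv(top_small_path, index=False)
        convergence = docking.score_convergence(
            score_records, sample_fraction=1.0, seed=rng_seed
        )
        conv_path = outdir / "convergence.csv"
        convergence.to_csv(conv_path, index=False)
        register("poses", poses_path)
        register("scored", scored_path)
        register("top_ranked", ranked_path)
        register("top_small", top_small_path)
        register("convergence", conv_path)
        record(stage, t0, n_scored=len(score_records))

        stage = "fingerprint"
        t0 = time.time()
        top_ids = ranked.sequences
        pose_by_id = {p.GetProp("_Name"): p for p in poses}
        top_poses = [pose_by_id[i] for i in top_ids]
        fper = InteractionFingerprinter(receptor=receptor, criteria=criteria)
        fper.fit(top_poses)
        fps = fper.transform(top_poses)
        fp_path = outdir / "fingerprints.csv"
        fper.to_matrix(fps).to_csv(fp_path)
        criteria_path = outdir / "criteria.json"
        criteria_path.write_text(criteria.to_json())
        register("fingerprints", fp_path)
        register("criteria", criteria_path)
        record(stage, t0, n_fingerprints=len(fps))

        stage = "cluster"
        t0 = time.time()
        assignment = cluster_fingerprints(
            fps, threshold=config.cluster_threshold,
            min_size=config.cluster_min_size,
        )
        clusters_path = outdir / "clusters.csv"
        assignment.to_frame().to_csv(clusters_path, index=False)
        report = cluster_report(assignment, fps, sequences=top_ids)
        report_path = outdir / "cluster_report.json"
        report_path.write_text(json.dumps(report, indent=2))
        register("clusters", clusters_path)
        register("cluster_report", report_path)
        record(stage, t0, n_clusters=assignment.n_clusters,
               n_outliers=len(assignment.outliers))

        stage = "enrich"
        t0 = time.time()
        scheme = enrichment.ResidueGroupScheme()
        groups = enrichment.group_frequencies(top_ids, scheme)
        groups = enrichment.normalize_by_group_size(groups, scheme)
        groups_path = outdir / "group_frequencies.csv"
        groups.table.to_csv(groups_path, index=False)
        residues = enrichment.residue_frequencies_with_rest(
            top_ids, min_count=config.min_count
        )
        residues_path = outdir / "residue_frequencies.csv"
        residues.table.to_csv(residues_path, index=False)
        props_df = pd.read_csv(props_path)
        top_df = props_df[props_df.sequence.isin(top_ids)]
        top10_df = props_df[props_df.sequence.isin(top_small.sequences)]
        comparison = enrichment.descriptor_comparison(summary, top_df, top10_df)
        comparison_path = outdir / "descriptor_comparison.csv"
        comparison.to_csv(comparison_path, index=False)
        register("group_frequencies", groups_path)
        register("residue_frequencies", residues_path)
        register("descriptor_comparison", comparison_path)
        record(stage, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PeplibError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["completed"] = len(manifest["stages"])
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _synthetic_plants(receptor, sequences, seed: int):
    """Deterministically assign planted interactions to each peptide.

    Each sequence gets 1-3 plants drawn from the feasible sites of the toy
    receptor by a sequence-keyed RNG, so the same sequence always receives
    the same binding mode regardless of library composition.
    """
    site_pool = [
        ("hbond_acceptor_from_ligand", "A:THR250"),
        ("hbond_acceptor_from_ligand", "A:GLU430"),
        ("hbond_donor_to_ligand", "A:ILE253"),
        ("hbond_donor_to_ligand", "A:ASN434"),
        ("hydrophobic", "A:MET252"),
        ("hydrophobic", "A:LEU314"),
        ("pi_pi", "A:HIS435"),
        ("cation_pi", "A:TYR436"),
        ("salt_bridge", "A:GLU430"),
        ("salt_bridge", "A:LYS340"),
    ]
    plants = []
    for seq in sequences:
        key = int.from_bytes(
            hashlib.sha256(f"{seed}:{seq}".encode()).digest()[:4], "big"
        )
        rng = np.random.default_rng(key)
        k = int(rng.integers(1, 4))
        idx = sorted(rng.choice(len(site_pool), size=k, replace=False))
        plants.append([site_pool[i] for i in idx])
    return plants
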