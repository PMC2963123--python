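"""End-to-end orchestration: filter -> distances -> trees -> pairing ->
congruence -> motif -> report.

The configuration is a plain key-value (YAML) file.  Every stage writes its
artifact to the output directory and records a SHA-256 in ``manifest.json``;
a rerun with identical inputs and seeds is byte-identical.  A stage failure
aborts the run, names the stage, and leaves a ``FAILED`` marker next to the
partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import align, congruence, context, io, motif, redundancy, simulate, treebuild

logger = logging.getLogger("phylopair.pipeline")

__all__ = ["PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} must be a key-value mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _distance_matrix(seqs: dict[str, str]) -> treebuild.DistanceMatrix:
    ids, ident = align.pairwise_identity_matrix(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = align.poisson_distance(max(ident[i, j], 1e-9))
    return treebuild.DistanceMatrix(ids, d)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Config keys (all optional unless noted):

    - ``seed`` (required): master seed for every random stage
    - ``simulate``: {n_taxa, mode, branch_jitter_sigma, root_length, ...}
      generates the two families; otherwise ``fasta_a``/``fasta_b`` plus
      ``pairs`` (TSV ``leafA leafB [operon]``) name user inputs
    - ``features``: feature TSV for operon pairing (overrides ``pairs``)
    - ``family_a`` / ``family_b``: family labels for context analysis
    - ``filter``: {cutoff, fragment_fraction} redundancy pre-filter
    - ``congruence``: {n_perm, alpha}
    - ``motif``: {width, n_starts}
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}}
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    if "seed" not in config:
        raise PipelineError("config", "a 'seed' key is required")
    seed = int(config["seed"])

    def record(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": path.name, "sha256": _sha256(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    def fail(stage: str, exc: Exception) -> "PipelineError":
        failed_marker.write_text(f"{stage}: {exc}\n")
        return PipelineError(stage, str(exc))

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        pairing = None
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            cfg = simulate.SimulationConfig(seed=seed, **sim_kwargs)
            pair = simulate.simulate_coevolving_pair(cfg)
            seqs_a, seqs_b, pairing = pair.seqs_a, pair.seqs_b, pair.pairing
            io.write_fasta(seqs_a, outdir / "family_a.faa")
            io.write_fasta(seqs_b, outdir / "family_b.faa")
            (outdir / "tree_a.generating.nwk").write_text(pair.tree_a.newick() + "\n")
            (outdir / "tree_b.generating.nwk").write_text(pair.tree_b.newick() + "\n")
            for n in ("family_a.faa", "family_b.faa", "tree_a.generating.nwk", "tree_b.generating.nwk"):
                record(stage, n, outdir / n)
        else:
            for key in ("fasta_a", "fasta_b"):
                if key not in config:
                    raise ValueError(f"config needs either 'simulate' or '{key}'")
                if not Path(config[key]).exists():
                    raise FileNotFoundError(f"missing input file: {config[key]}")
            seqs_a = io.read_fasta(config["fasta_a"])
            seqs_b = io.read_fasta(config["fasta_b"])
    except PipelineError:
        raise
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- pairing from genome context -------------------------------------
    if "features" in config:
        stage = "context"
        try:
            feats = context.read_features_tsv(config["features"])
            fam_a, fam_b = config.get("family_a", "arsA"), config.get("family_b", "cstA")
            profile = context.association_profile(feats, fam_a, fam_b)
            pairing = context.operon_pairing(feats, fam_a, fam_b)
            (outdir / "association_profile.json").write_text(
                json.dumps(
                    {
                        "family_a": profile.family_a,
                        "family_b": profile.family_b,
                        "n_same_operon": profile.n_same_operon,
                        "n_elsewhere_in_genome": profile.n_elsewhere_in_genome,
                        "n_absent": profile.n_absent,
                        "per_genome": profile.per_genome,
                    },
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
            record(stage, "association_profile.json", outdir / "association_profile.json")
        except Exception as exc:
            raise fail(stage, exc) from exc
    elif pairing is None and "pairs" in config:
        stage = "pairing"
        try:
            rows = [
                ln.split("\t")
                for ln in Path(config["pairs"]).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
            pairing = congruence.LeafPairing(
                tuple((r[0], r[1]) for r in rows),
                tuple(r[2] for r in rows) if all(len(r) > 2 for r in rows) else None,
            )
        except Exception as exc:
            raise fail(stage, exc) from exc

    # ---- redundancy filter ------------------------------------------------
    if "filter" in config:
        stage = "filter"
        try:
            fcfg = config["filter"] or {}
            seqs_a = redundancy.filter_redundant(
                seqs_a,
                cutoff=fcfg.get("cutoff", redundancy.DEFAULT_CUTOFF),
                fragment_fraction=fcfg.get("fragment_fraction", redundancy.DEFAULT_FRAGMENT_FRACTION),
            )
            seqs_b = redundancy.filter_redundant(
                seqs_b,
                cutoff=fcfg.get("cutoff", redundancy.DEFAULT_CUTOFF),
                fragment_fraction=fcfg.get("fragment_fraction", redundancy.DEFAULT_FRAGMENT_FRACTION),
            )
            io.write_fasta(seqs_a, outdir / "family_a.filtered.faa")
            io.write_fasta(seqs_b, outdir / "family_b.filtered.faa")
            record(stage, "family_a.filtered.faa", outdir / "family_a.filtered.faa")
            record(stage, "family_b.filtered.faa", outdir / "family_b.filtered.faa")
        except Exception as exc:
            raise fail(stage, exc) from exc

    # ---- distances and trees ----------------------------------------------
    stage = "trees"
    try:
        trees = {}
        for label, seqs in (("a", seqs_a), ("b", seqs_b)):
            dm = _distance_matrix(seqs)
            io.write_distance_tsv(dm.ids, dm.matrix, outdir / f"family_{label}.dist.tsv")
            tree = treebuild.neighbor_joining(dm)
            (outdir / f"family_{label}.nwk").write_text(tree.newick() + "\n")
            trees[label] = tree
            record(stage, f"family_{label}.dist.tsv", outdir / f"family_{label}.dist.tsv")
            record(stage, f"family_{label}.nwk", outdir / f"family_{label}.nwk")
    except Exception as exc:
        raise fail(stage, exc) from exc

    # ---- congruence --------------------------------------------------------
    if pairing is not None and len(pairing) >= congruence.MIN_PAIRS_TEST:
        stage = "congruence"
        try:
            ccfg = config.get("congruence", {}) or {}
            result = congruence.permutation_test(
                trees["a"],
                trees["b"],
                pairing,
                n_perm=int(ccfg.get("n_perm", 999)),
                seed=seed,
                alpha=float(ccfg.get("alpha", 0.05)),
            )
            (outdir / "congruence.json").write_text(
                json.dumps(asdict(result), indent=2, sort_keys=True) + "\n"
            )
            record(stage, "congruence.json", outdir / "congruence.json")
        except Exception as exc:
            raise fail(stage, exc) from exc

    # ---- motif -------------------------------------------------------------
    if "motif" in config:
        stage = "motif"
        try:
            mcfg = config["motif"] or {}
            model = motif.discover_motif_em(
                list(seqs_a.values()),
                width=int(mcfg.get("width", 12)),
                n_starts=int(mcfg.get("n_starts", 10)),
                seed=seed,
            )
            ic = model.information_content()
            with open(outdir / "motif_a.tsv", "w", encoding="utf-8") as fh:
                fh.write("position\t" + "\t".join(align.AMINO_ACIDS) + "\tIC_bits\n")
                for i in range(model.width):
                    freqs = "\t".join(f"{x:.6f}" for x in model.frequencies[i])
                    fh.write(f"{i + 1}\t{freqs}\t{ic[i]:.4f}\n")
                fh.write(f"#consensus\t{model.consensus()}\n")
            record(stage, "motif_a.tsv", outdir / "motif_a.tsv")
        except Exception as exc:
            raise fail(stage, exc) from exc

    manifest["seed"] = seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(manifest["artifacts"]), outdir)
    return manifest
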