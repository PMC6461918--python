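"""Readers and writers for the package's delimited-text interchange formats.

Conventions (documented in every file header this module writes):

* outputs are tab-separated; inputs may be comma- or tab-separated
  (autodetected);
* genetic map positions are stored in Morgans;
* indices in files are 1-based, ids are preferred over indices wherever
  both exist;
* writers emit ``#``-prefixed header comments describing the columns, and
  readers skip them.

Frontiers round-trip through JSON (exact float preservation); mating
plans, trajectories and relationship matrices through TSV.  A small
:func:`make_fixture_set` emits a simulated founder population (genotypes,
map, effects, phenotypes, GEBVs) as text files for demonstrations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    BreedingValues,
    ContributionVector,
    GenotypeMatrix,
    MarkerEffects,
    RelationshipMatrix,
)
from .mating import MatingPlan, MatingObjectives
from .pareto import FrontierSolution, ObjectiveVector, ParetoFrontier

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_gebv",
    "write_gebv",
    "read_effects",
    "write_effects",
    "read_grm",
    "write_grm",
    "read_frontier",
    "write_frontier",
    "read_plan",
    "write_plan",
    "write_trajectory",
    "write_manifest",
    "file_digest",
    "make_fixture_set",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path, sep=_sniff_sep(path), comment="#", float_precision="round_trip"
    )


def _write_header(fh, lines: Sequence[str]) -> None:
    for line in lines:
        fh.write(f"# {line}\n")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path, format: str = "csv", map_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read a genotype matrix from delimited text or VCF.

    Delimited layout: first column the individual id, header row of
    marker ids, dosages in {0, 1, 2}.  An optional companion map file
    supplies (marker, chromosome, position-in-Morgans); without one a
    trivial single-chromosome map is assumed.  VCF input (requires pysam)
    is restricted to biallelic SNPs with a GT field; dosage is the ALT
    allele count and missing genotypes are rejected.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format != "csv":
        raise ValueError(f"unknown genotype format {format!r}")
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    markers = [str(c) for c in df.columns[1:]]
    dosages = df.iloc[:, 1:].to_numpy()
    bad = ~np.isin(dosages, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid dosage {dosages[r, c]!r} at data row {r + 1}, "
            f"column {markers[c]!r}"
        )
    chromosomes = positions = None
    if map_path is not None:
        mp = _read_table(map_path)
        mp.columns = [c.lower() for c in mp.columns]
        mp = mp.set_index(mp.columns[0])
        missing = [m for m in markers if m not in mp.index]
        if missing:
            raise ValueError(f"{map_path}: markers missing from map: {missing[:5]}")
        mp = mp.loc[markers]
        chromosomes = mp.iloc[:, 0].to_numpy()
        positions = mp.iloc[:, 1].to_numpy(dtype=float)
    return GenotypeMatrix.from_dosages(
        dosages.astype(np.int8),
        chromosomes=chromosomes,
        positions=positions,
        individual_ids=ids,
        marker_ids=markers,
    )


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires pysam") from exc
    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    markers, chroms, positions, rows = [], [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"{path}: non-biallelic record at {rec.chrom}:{rec.pos}"
            )
        row = []
        for sample in ids:
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                raise ValueError(
                    f"{path}: missing GT at {rec.chrom}:{rec.pos} for {sample}"
                )
            row.append(sum(int(a > 0) for a in gt))
        rows.append(row)
        markers.append(rec.id or f"{rec.chrom}_{rec.pos}")
        chroms.append(rec.chrom)
        positions.append(rec.pos * 1e-8)  # bp -> Morgans at 1 cM/Mb, nominal
    if not rows:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix.from_dosages(
        np.array(rows, dtype=np.int8).T,
        chromosomes=np.array(chroms),
        positions=np.array(positions),
        individual_ids=ids,
        marker_ids=markers,
    )


def write_genotypes(
    G: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, ["genotype dosages: rows individuals, columns markers,",
                           "values = counts of the alternate allele in {0,1,2}"])
        fh.write("id\t" + "\t".join(G.marker_ids) + "\n")
        for i, ind in enumerate(G.individual_ids):
            fh.write(ind + "\t" + "\t".join(str(int(d)) for d in G.dosages[i]) + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            _write_header(fh, ["genetic map; position in Morgans"])
            fh.write("marker\tchromosome\tposition_morgan\n")
            for m, c, p in zip(G.marker_ids, G.chromosomes, G.positions):
                fh.write(f"{m}\t{c}\t{float(p)!r}\n")


# ---------------------------------------------------------------------------
# breeding values / effects / GRM


def read_gebv(path: str | Path, maximize: Sequence[bool] | None = None) -> BreedingValues:
    """Breeding-value table: first column id, one column per trait."""
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    traits = [str(c) for c in df.columns[1:]]
    if not traits:
        raise ValueError(f"{path}: no trait columns")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return BreedingValues(values, traits, maximize=maximize, individual_ids=ids)


def write_gebv(bv: BreedingValues, path: str | Path) -> None:
    ids = bv.individual_ids or [f"ind{i + 1}" for i in range(bv.n_individuals)]
    with open(path, "w") as fh:
        _write_header(fh, ["breeding values: rows individuals, one column per trait"])
        fh.write("id\t" + "\t".join(bv.trait_names) + "\n")
        for i, ind in enumerate(ids):
            fh.write(ind + "\t" + "\t".join(repr(float(v)) for v in bv.values[i]) + "\n")


def read_effects(path: str | Path) -> MarkerEffects:
    df = _read_table(path)
    markers = df.iloc[:, 0].astype(str).tolist()
    traits = [str(c) for c in df.columns[1:]]
    return MarkerEffects(
        df.iloc[:, 1:].to_numpy(dtype=float), traits, marker_ids=markers
    )


def write_effects(E: MarkerEffects, path: str | Path) -> None:
    ids = E.marker_ids or [f"m{i + 1}" for i in range(E.n_markers)]
    with open(path, "w") as fh:
        _write_header(fh, ["additive marker effects: rows markers, one column per trait"])
        fh.write("marker\t" + "\t".join(E.trait_names) + "\n")
        for i, m in enumerate(ids):
            fh.write(m + "\t" + "\t".join(repr(float(v)) for v in E.beta[i]) + "\n")


def read_grm(path: str | Path) -> RelationshipMatrix:
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    A = df.iloc[:, 1:].to_numpy(dtype=float)
    cols = [str(c) for c in df.columns[1:]]
    if cols != ids:
        raise ValueError(f"{path}: row and column ids differ")
    return RelationshipMatrix(A, ids)


def write_grm(A: RelationshipMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, ["additive genomic relationship matrix (square, symmetric)"])
        fh.write("id\t" + "\t".join(A.individual_ids) + "\n")
        for i, ind in enumerate(A.individual_ids):
            fh.write(ind + "\t" + "\t".join(repr(float(v)) for v in A.A[i]) + "\n")


# ---------------------------------------------------------------------------
# frontiers


def write_frontier(
    F: ParetoFrontier,
    path: str | Path,
    tsv_path: str | Path | None = None,
    objective_names: Sequence[str] | None = None,
) -> None:
    """Write a contribution frontier as JSON (exact) + optional TSV summary.

    One JSON entry per solution: scalarization weights, objective vector,
    and the sparse non-zero contributions keyed by 1-based candidate
    index.
    """
    if len(F) == 0:
        raise ValueError("empty frontier")
    n_obj = len(F.maximize)
    names = list(objective_names) if objective_names else [
        f"obj{t + 1}" for t in range(n_obj)
    ]
    first = F[0].decision
    ids = getattr(first, "individual_ids", None)
    m = first.c.size if isinstance(first, ContributionVector) else None
    payload = {
        "format": "moob-frontier",
        "objective_names": names,
        "maximize": [bool(b) for b in F.maximize],
        "n_candidates": m,
        "individual_ids": ids,
        "solutions": [],
    }
    for sol in F:
        c = sol.decision.c
        entry = {
            "weights": None
            if sol.scalarization_weights is None
            else [float(w) for w in sol.scalarization_weights],
            "objectives": [float(v) for v in sol.objectives.values],
            "contributions": {
                str(i + 1): float(c[i]) for i in np.flatnonzero(c > 0)
            },
        }
        payload["solutions"].append(entry)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            _write_header(fh, [
                "Pareto frontier, one row per solution;",
                "contributions column: 1-based index:value pairs, comma separated",
            ])
            wn = [f"w_{n}" for n in names]
            fh.write("\t".join(["solution", *wn, *names, "contributions"]) + "\n")
            for s_idx, sol in enumerate(F):
                w = sol.scalarization_weights
                wcols = ["NA"] * n_obj if w is None else [repr(float(x)) for x in w]
                ocols = [repr(float(v)) for v in sol.objectives.values]
                c = sol.decision.c
                sparse = ",".join(
                    f"{i + 1}:{c[i]:.6g}" for i in np.flatnonzero(c > 1e-10)
                )
                fh.write("\t".join([str(s_idx + 1), *wcols, *ocols, sparse]) + "\n")


def read_frontier(path: str | Path) -> ParetoFrontier:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "moob-frontier":
        raise ValueError(f"{path}: not a frontier file")
    maximize = np.array(payload["maximize"], dtype=bool)
    m = payload["n_candidates"]
    ids = payload.get("individual_ids")
    solutions = []
    for entry in payload["solutions"]:
        c = np.zeros(m)
        for key, val in entry["contributions"].items():
            c[int(key) - 1] = val
        if abs(c.sum() - 1.0) > 1e-9:
            c = c / c.sum()
        sol = FrontierSolution(
            decision=ContributionVector(c, ids),
            objectives=ObjectiveVector(np.array(entry["objectives"]), maximize),
            scalarization_weights=None
            if entry["weights"] is None
            else np.array(entry["weights"]),
        )
        solutions.append(sol)
    return ParetoFrontier(solutions, deduplicated=True)


# ---------------------------------------------------------------------------
# mating plans and trajectories


def write_plan(
    plan: MatingPlan,
    path: str | Path,
    objectives: MatingObjectives | None = None,
    individual_ids: Sequence[str] | None = None,
) -> None:
    """Plan TSV: one row per distinct cross (1-based parent indices,
    multiplicity); plan-level objectives go to ``<path>.objectives.json``."""
    with open(path, "w") as fh:
        _write_header(fh, ["mating plan; parent indices are 1-based"])
        fh.write("parent_i\tparent_j\tmultiplicity\n")
        for i, j, mult in plan.with_multiplicity():
            fh.write(f"{i + 1}\t{j + 1}\t{mult}\n")
    if objectives is not None:
        side = {
            "gain": [float(v) for v in objectives.gain],
            "cross_variance": [float(v) for v in objectives.cross_variance],
            "inbreeding": float(objectives.inbreeding),
        }
        with open(str(path) + ".objectives.json", "w") as fh:
            json.dump(side, fh, indent=1)
            fh.write("\n")


def read_plan(path: str | Path) -> MatingPlan:
    df = _read_table(path)
    crosses: list[tuple[int, int]] = []
    for _, row in df.iterrows():
        crosses.extend(
            [(int(row.iloc[0]) - 1, int(row.iloc[1]) - 1)] * int(row.iloc[2])
        )
    return MatingPlan(crosses)


def write_trajectory(trajectory: pd.DataFrame, path: str | Path) -> None:
    """Trajectory TSV: cycle, inbreeding, then per-trait mean/var/gain."""
    with open(path, "w") as fh:
        _write_header(fh, [
            "breeding trajectory: one row per cycle;",
            "inbreeding = mean kinship vs the base population;",
            "gain_* in base-population genetic SD units",
        ])
        trajectory.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifests and fixtures


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: Sequence[str | Path],
    outputs: Sequence[str | Path],
    wall_time: float,
) -> None:
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "wall_time_seconds": round(wall_time, 3),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def make_fixture_set(outdir: str | Path, seed: int = 0, pop_size: int = 30,
                     n_markers_per_chrom: int = 40) -> dict[str, Path]:
    """Emit a small simulated founder population as text fixtures.

    Writes genotypes.tsv, map.tsv, effects.tsv, phenotypes.tsv, gebv.tsv
    and grm.tsv into ``outdir`` and returns their paths.
    """
    from .core import compute_relationship
    from .sim import SimulationConfig, make_founders, predict_gebv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        pop_size=pop_size,
        n_markers_per_chrom=n_markers_per_chrom,
        n_qtl_per_chrom=max(2, n_markers_per_chrom // 5),
        n_opposite_sign=max(1, n_markers_per_chrom // 10),
        burnin_random_mating=20,
    )
    state = make_founders(cfg, seed)
    G = state.genotypes()
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "map": outdir / "map.tsv",
        "effects": outdir / "effects.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "gebv": outdir / "gebv.tsv",
        "grm": outdir / "grm.tsv",
    }
    write_genotypes(G, paths["genotypes"], map_path=paths["map"])
    write_effects(
        MarkerEffects(
            state.architecture.effects.beta,
            state.architecture.effects.trait_names,
            marker_ids=G.marker_ids,
        ),
        paths["effects"],
    )
    phen = BreedingValues(
        state.phenotypes,
        state.architecture.effects.trait_names,
        individual_ids=G.individual_ids,
    )
    write_gebv(phen, paths["phenotypes"])
    gebv, _ = predict_gebv(state, cfg.h2)
    gebv.individual_ids = list(G.individual_ids)
    write_gebv(gebv, paths["gebv"])
    write_grm(compute_relationship(G), paths["grm"])
    return paths
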