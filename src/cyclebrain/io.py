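"""File formats: NIfTI session stacks, TSV tables, study manifests.

All tables are tab-separated UTF-8 with dot decimals.  Volumetric stacks are
stored as one NIfTI file per session plus a mask NIfTI; vertex stacks as a
sessions-by-vertices TSV matrix plus an edge-list TSV.  A YAML study
manifest ties sessions, mask/adjacency and the hormone table together.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .hormones import HormoneSeries, read_hormone_tsv, write_hormone_tsv
from .phantom import SessionStack, VertexGeometry, VolumeGeometry

__all__ = [
    "StudyManifest",
    "write_stack_nifti",
    "read_stack_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
    "write_vertex_stack",
    "read_vertex_stack",
    "write_components_tsv",
    "write_scores_tsv",
    "write_assoc_tsv",
    "write_gam_tsv",
]


def write_mask_nifti(geometry: VolumeGeometry, path) -> None:
    affine = np.diag([geometry.voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(geometry.mask.astype(np.uint8), affine), str(path))


def read_mask_nifti(path) -> VolumeGeometry:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    voxel_mm = float(img.header.get_zooms()[0])
    return VolumeGeometry(shape=mask.shape, voxel_mm=voxel_mm, mask=mask)


def write_stack_nifti(stack: SessionStack, out_dir, prefix: str | None = None):
    """One NIfTI per session; returns a manifest DataFrame of written rows."""
    geom = stack.geometry
    if geom.kind != "volume":
        raise ValueError("NIfTI output requires a volumetric stack")
    os.makedirs(out_dir, exist_ok=True)
    prefix = prefix or stack.individual_id
    affine = np.diag([geom.voxel_mm] * 3 + [1.0])
    rows = []
    for day, row in zip(stack.days, stack.data):
        vol = geom.unmask(row).astype(np.float32)
        path = os.path.join(out_dir, f"{prefix}_day{int(day):03d}.nii.gz")
        nib.save(nib.Nifti1Image(vol, affine), path)
        rows.append(
            {"individual_id": stack.individual_id, "day": int(day), "path": path}
        )
    return pd.DataFrame(rows)


def read_stack_nifti(
    rows: pd.DataFrame, geometry: VolumeGeometry, individual_id: str
) -> SessionStack:
    rows = rows.sort_values("day")
    data = []
    for path in rows["path"]:
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        if vol.shape != tuple(geometry.shape):
            raise ValueError(f"{path}: shape {vol.shape} != mask {geometry.shape}")
        data.append(vol[geometry.mask])
    return SessionStack(
        individual_id=individual_id,
        days=rows["day"].to_numpy(),
        data=np.stack(data),
        geometry=geometry,
    )


def write_vertex_stack(stack: SessionStack, matrix_path, edges_path=None) -> None:
    geom = stack.geometry
    if geom.kind != "vertex":
        raise ValueError("vertex output requires a vertex stack")
    frame = pd.DataFrame(stack.data)
    frame.insert(0, "day", stack.days)
    frame.insert(0, "individual_id", stack.individual_id)
    frame.to_csv(matrix_path, sep="\t", index=False, float_format="%.17g")
    if edges_path is not None:
        pd.DataFrame(geom.edges, columns=["vertex_a", "vertex_b"]).to_csv(
            edges_path, sep="\t", index=False
        )


def read_vertex_stack(matrix_path, edges_path) -> SessionStack:
    frame = pd.read_csv(matrix_path, sep="\t", float_precision="round_trip")
    edges = pd.read_csv(edges_path, sep="\t")[["vertex_a", "vertex_b"]].to_numpy()
    data = frame.drop(columns=["individual_id", "day"]).to_numpy(dtype=float)
    geom = VertexGeometry(n_vertices=data.shape[1], edges=edges)
    return SessionStack(
        individual_id=str(frame["individual_id"].iloc[0]),
        days=frame["day"].to_numpy(),
        data=data,
        geometry=geom,
    )


@dataclass
class StudyManifest:
    """Session table plus geometry and hormone-table paths for one study."""

    sessions: pd.DataFrame          # individual_id, day, path
    hormone_path: str
    measure: str = "volume"         # "volume" | "thickness"
    mask_path: str | None = None
    adjacency_path: str | None = None

    @classmethod
    def load(cls, yaml_path) -> "StudyManifest":
        with open(yaml_path) as fh:
            spec = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(yaml_path))

        def _abs(p):
            return p if p is None or os.path.isabs(p) else os.path.join(base, p)

        sessions = pd.read_csv(_abs(spec["sessions"]), sep="\t")
        return cls(
            sessions=sessions,
            hormone_path=_abs(spec["hormones"]),
            measure=spec.get("measure", "volume"),
            mask_path=_abs(spec.get("mask")),
            adjacency_path=_abs(spec.get("adjacency")),
        )

    def validate(self) -> list[str]:
        """Collect all consistency problems (empty list = valid)."""
        problems = []
        required = {"individual_id", "day", "path"}
        missing_cols = required - set(self.sessions.columns)
        if missing_cols:
            return [f"session table missing columns: {sorted(missing_cols)}"]
        dup = self.sessions.duplicated(subset=["individual_id", "day"])
        if dup.any():
            problems.append(
                f"duplicate (individual_id, day) rows: "
                f"{self.sessions[dup][['individual_id', 'day']].values.tolist()}"
            )
        if self.measure == "volume" and not self.mask_path:
            problems.append("volumetric study requires a mask path")
        if self.measure == "thickness" and not self.adjacency_path:
            problems.append("thickness study requires an adjacency path")
        try:
            hormones = read_hormone_tsv(self.hormone_path)
        except Exception as err:  # noqa: BLE001 - report, don't crash
            return problems + [f"cannot read hormone table: {err}"]
        by_id = {h.individual_id: set(h.day.tolist()) for h in hormones}
        for ind, grp in self.sessions.groupby("individual_id"):
            days = set(int(d) for d in grp["day"])
            if ind not in by_id:
                problems.append(f"no hormone rows for individual {ind!r}")
            elif days - by_id[ind]:
                problems.append(
                    f"individual {ind!r}: session days {sorted(days - by_id[ind])} "
                    f"have no hormone row"
                )
        for path in self.sessions["path"]:
            if not os.path.exists(path):
                problems.append(f"missing session file: {path}")
        return problems

    def exclude_sessions(
        self, exclusions: list[tuple[str, int]]
    ) -> "StudyManifest":
        """Drop listed (individual_id, day) sessions from all analyses."""
        sessions = self.sessions
        for ind, day in exclusions:
            hit = (sessions["individual_id"] == ind) & (sessions["day"] == int(day))
            if not hit.any():
                raise KeyError(f"unknown session ({ind!r}, day {day})")
            sessions = sessions[~hit]
        return replace(self, sessions=sessions.reset_index(drop=True))

    def load_data(self) -> tuple[list[SessionStack], list[HormoneSeries]]:
        """Read stacks and day-aligned hormone series (order of appearance)."""
        problems = self.validate()
        if problems:
            raise ValueError("manifest validation failed:\n- " + "\n- ".join(problems))
        if self.measure == "volume":
            geometry = read_mask_nifti(self.mask_path)
            stacks = [
                read_stack_nifti(grp, geometry, str(ind))
                for ind, grp in self.sessions.groupby("individual_id", sort=False)
            ]
        else:
            stacks = []
            for ind, grp in self.sessions.groupby("individual_id", sort=False):
                paths = grp["path"].unique()
                if len(paths) != 1:
                    raise ValueError(
                        f"thickness study expects one matrix per individual, "
                        f"got {len(paths)} for {ind!r}"
                    )
                stacks.append(read_vertex_stack(paths[0], self.adjacency_path))
        hormones = []
        by_id = {h.individual_id: h for h in read_hormone_tsv(self.hormone_path)}
        for s in stacks:
            h = by_id[s.individual_id]
            keep = np.isin(h.day, s.days)
            hormones.append(
                HormoneSeries(
                    individual_id=h.individual_id,
                    day=h.day[keep],
                    estradiol=h.estradiol[keep],
                    progesterone=h.progesterone[keep],
                    ratio=h.ratio[keep],
                    phase=h.phase[keep],
                )
            )
        return stacks, hormones


# ---------------------------------------------------------------------------
# result tables


def write_components_tsv(patterns, path) -> None:
    pd.DataFrame(
        {
            "component": [p.index for p in patterns],
            "singular_value": [p.singular_value for p in patterns],
            "variance_fraction": [p.variance_fraction for p in patterns],
            "retained": [p.retained for p in patterns],
        }
    ).to_csv(path, sep="\t", index=False)


def write_scores_tsv(patterns, blocks, days_by_id, path) -> None:
    rows = []
    for p in patterns:
        for ind, sl in blocks:
            for day, raw, std in zip(
                days_by_id[ind], p.temporal[sl], p.temporal_std[sl]
            ):
                rows.append(
                    {
                        "individual_id": ind,
                        "day": int(day),
                        "component": p.index,
                        "score": raw,
                        "score_std": std,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_assoc_tsv(results, path, measure: str = "volume") -> None:
    pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "measure": measure,
                "component": r.component,
                "predictor": r.predictor,
                "beta0": r.beta0,
                "beta1": r.beta1,
                "p": r.p_beta,
                "p_fdr": r.p_beta_fdr,
                "rho": r.rho,
                "p_rho": r.p_rho,
                "p_rho_fdr": r.p_rho_fdr,
                "n": r.n,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_gam_tsv(fits, path, alpha: float = 0.05) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": f.individual_id,
                "component": f.component,
                "edf": f.edf,
                "F": f.f_stat,
                "p": f.p_value,
                "p_fdr": f.p_fdr,
                "fluctuates": (f.p_fdr is not None and f.p_fdr < alpha),
            }
            for f in fits
        ]
    ).to_csv(path, sep="\t", index=False)


def write_spatial_maps(patterns, geometry, out_dir, thresholder=None) -> None:
    """Write retained spatial patterns as NIfTI (volume) or TSV (vertex)."""
    os.makedirs(out_dir, exist_ok=True)
    for p in patterns:
        maps = {"raw": p.spatial}
        if thresholder is not None:
            maps["display"] = thresholder(p.spatial)
        for tag, vec in maps.items():
            if geometry.kind == "volume":
                affine = np.diag([geometry.voxel_mm] * 3 + [1.0])
                img = nib.Nifti1Image(
                    geometry.unmask(vec).astype(np.float32), affine
                )
                nib.save(
                    img, os.path.join(out_dir, f"component{p.index}_{tag}.nii.gz")
                )
            else:
                np.savetxt(
                    os.path.join(out_dir, f"component{p.index}_{tag}.tsv"),
                    vec,
                    delimiter="\t",
                )

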