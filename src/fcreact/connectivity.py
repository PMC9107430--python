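"""Subcortico-cortical Fisher-z connectivity matrices.

Each subject-session yields two matrices of Fisher r-to-z transformed Pearson
correlations: a dopaminergic network (cortical x dopaminergic ROIs) and a
cholinergic network (cortical x cholinergic ROIs).  No cortico-cortical or
subcortico-subcortical edges are formed.  Edges are flattened in a single
canonical order — dopaminergic system first, subcortical-major within a
system — shared by every subject and session so that downstream resampling
and reporting are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import SessionTimeSeries

__all__ = [
    "Edge",
    "ConnectivitySet",
    "R_CLIP",
    "edge_fc",
    "build_networks",
    "mean_network_strength",
    "ach_da_difference",
    "connectivity_long",
]

#: Correlations are clipped at |r| = 1 - R_CLIP before atanh so z stays finite.
R_CLIP = 1e-12


class Edge(NamedTuple):
    system: str          # "da" | "ach"
    subcortical: str
    cortical: str


@dataclass
class ConnectivitySet:
    """Fisher-z connectivity of one subject-session.

    ``da_z`` is cortical x dopaminergic, ``ach_z`` cortical x cholinergic.
    ``edge_index`` flattens both matrices (DA first, subcortical-major).
    """

    subject_id: str
    session: str
    da_z: np.ndarray
    ach_z: np.ndarray
    edge_index: list[Edge]

    def validate(self) -> None:
        n_edges = self.da_z.size + self.ach_z.size
        if len(self.edge_index) != n_edges:
            raise ValueError("edge_index length does not match matrix sizes")
        if not (np.all(np.isfinite(self.da_z)) and np.all(np.isfinite(self.ach_z))):
            raise ValueError("non-finite connectivity values")

    def flatten(self) -> np.ndarray:
        """Edge values in ``edge_index`` order (DA first, subcortical-major)."""
        return np.concatenate([self.da_z.T.ravel(), self.ach_z.T.ravel()])


def make_edge_index(da_labels: list[str], ach_labels: list[str],
                    cortical: list[str]) -> list[Edge]:
    """Canonical flattening: DA then ACh, subcortical-major, cortical-minor."""
    index = [Edge("da", s, c) for s in da_labels for c in cortical]
    index += [Edge("ach", s, c) for s in ach_labels for c in cortical]
    return index


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def edge_fc(x, y) -> float:
    """Fisher-z connectivity of one ROI pair: ``atanh(clip(pearson(x, y)))``.

    Correlations are clipped at ``1 - 1e-12`` in magnitude so perfectly
    correlated (degenerate) pairs still yield a finite value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("time series must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("time series must have length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance ROI")
    r = np.clip(_pearson(x, y), -1.0 + R_CLIP, 1.0 - R_CLIP)
    return float(np.arctanh(r))


def build_networks(ts: SessionTimeSeries) -> ConnectivitySet:
    """Map every (cortical, subcortical) ROI pair through :func:`edge_fc`.

    Vectorised over pairs; identical to calling :func:`edge_fc` per pair.
    """
    ts.validate()
    cort_idx = [i for i, l in enumerate(ts.roi_labels)
                if ts.roi_partition[l] == "cortical"]
    da_idx = [i for i, l in enumerate(ts.roi_labels)
              if ts.roi_partition[l] == "dopaminergic"]
    ach_idx = [i for i, l in enumerate(ts.roi_labels)
               if ts.roi_partition[l] == "cholinergic"]
    v = np.asarray(ts.values, dtype=float)
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI: {bad} "
                         f"({ts.subject_id}/{ts.session})")
    r_full = np.corrcoef(v, rowvar=False)
    r_full = np.clip(r_full, -1.0 + R_CLIP, 1.0 - R_CLIP)
    z = np.arctanh(r_full)
    cs = ConnectivitySet(
        subject_id=ts.subject_id,
        session=ts.session,
        da_z=z[np.ix_(cort_idx, da_idx)],
        ach_z=z[np.ix_(cort_idx, ach_idx)],
        edge_index=make_edge_index(
            [ts.roi_labels[i] for i in da_idx],
            [ts.roi_labels[i] for i in ach_idx],
            [ts.roi_labels[i] for i in cort_idx]),
    )
    cs.validate()
    return cs


def mean_network_strength(cs: ConnectivitySet, system: str) -> float:
    """Arithmetic mean over all Fisher-z entries of one network matrix."""
    sysl = system.lower()
    if sysl == "da":
        return float(cs.da_z.mean())
    if sysl == "ach":
        return float(cs.ach_z.mean())
    raise ValueError(f"unknown system {system!r} (expected 'da' or 'ach')")


def ach_da_difference(cs: ConnectivitySet) -> float:
    """Relative cholinergic-vs-dopaminergic activity: mean ACh-z minus mean DA-z."""
    return mean_network_strength(cs, "ach") - mean_network_strength(cs, "da")


def connectivity_long(sets: list[ConnectivitySet]) -> pd.DataFrame:
    """Long-format table: subject_id, session, system, subcortical, cortical, z."""
    rows = []
    for cs in sets:
        flat = cs.flatten()
        for edge, z in zip(cs.edge_index, flat):
            rows.append((cs.subject_id, cs.session, edge.system,
                         edge.subcortical, edge.cortical, z))
    return pd.DataFrame(
        rows, columns=["subject_id", "session", "system",
                       "subcortical", "cortical", "z"])
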