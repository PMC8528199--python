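"""Automated SEEG re-referencing operators.

Six schemes: raw passthrough, common average reference (CAR), gray/white
matter reference (GWR), electrode shaft reference (ESR), bipolar reference,
and Laplacian reference.  Every operator is a fixed linear map in channel
space, built once as a matrix and applied to 2-D (channels x samples) or
3-D (trials x channels x time) arrays, which makes linearity and exact
common-mode rejection structural rather than incidental.

Conventions (documented package decisions, see docs/methods.md):

* bipolar derivations are deep-minus-superficial (contact i minus contact
  i+1); the most superficial contact of each shaft yields no output channel;
* Laplacian end contacts default to ``single_neighbor`` (referenced to their
  only neighbor, bipolar-like); ``drop_ends`` removes them instead;
* excluded (bad) channels are removed before any averaging and break
  adjacency: contacts across a gap are never paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_montage import ChannelInfo, EpochSet

SCHEMES = ("raw", "car", "gwr", "esr", "bipolar", "laplacian")

__all__ = [
    "SCHEMES",
    "RerefScheme",
    "apply_car",
    "apply_gwr",
    "apply_esr",
    "apply_bipolar",
    "apply_laplacian",
    "apply_scheme",
    "reref_matrix",
]


@dataclass(frozen=True)
class RerefScheme:
    name: str
    edge_policy: str = "single_neighbor"
    excluded_channels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.name not in SCHEMES:
            raise ValueError(f"unknown re-referencing scheme {self.name!r}")
        if self.edge_policy not in ("single_neighbor", "drop_ends"):
            raise ValueError(f"unknown edge policy {self.edge_policy!r}")


def _included(montage, excluded):
    keep = [i for i, c in enumerate(montage) if c.channel_id not in excluded]
    if not keep:
        raise ValueError("all channels excluded")
    return keep


def _neighbors(montage, keep):
    """Adjacency among included channels: same shaft, contact_index +/- 1."""
    pos = {(montage[i].shaft, montage[i].contact_index): i for i in keep}
    nb = {}
    for i in keep:
        c = montage[i]
        nb[i] = (
            pos.get((c.shaft, c.contact_index - 1)),
            pos.get((c.shaft, c.contact_index + 1)),
        )
    return nb


def reref_matrix(scheme: RerefScheme, montage: list[ChannelInfo]):
    """Build the channel-space transform for ``scheme``.

    Returns ``(W, out_montage)`` with ``W`` of shape
    (n_out, n_in) acting on the full input channel set; excluded channels
    have zero columns and produce no output rows.
    """
    excluded = set(scheme.excluded_channels)
    keep = _included(montage, excluded)
    n_in = len(montage)
    name = scheme.name

    if name == "raw":
        W = np.zeros((len(keep), n_in))
        W[np.arange(len(keep)), keep] = 1.0
        return W, [montage[i] for i in keep]

    if name == "car":
        if len(keep) < 2:
            raise ValueError("CAR needs at least 2 included channels")
        W = np.zeros((len(keep), n_in))
        W[np.arange(len(keep)), keep] = 1.0
        W[:, keep] -= 1.0 / len(keep)
        return W, [montage[i] for i in keep]

    if name == "gwr":
        gray = [i for i in keep if montage[i].tissue == "gray"]
        white = [i for i in keep if montage[i].tissue == "white"]
        unknown = [i for i in keep if montage[i].tissue == "unknown"]
        if unknown:
            warnings.warn(
                f"{len(unknown)} channel(s) with unknown tissue referenced "
                "to the global average and excluded from tissue averages"
            )
        W = np.zeros((len(keep), n_in))
        labeled = gray + white
        if not labeled:
            raise ValueError("GWR needs at least one gray or white channel")
        for r, i in enumerate(keep):
            W[r, i] += 1.0
            group = gray if montage[i].tissue == "gray" else (
                white if montage[i].tissue == "white" else labeled)
            if not group:
                raise ValueError(
                    f"no channels in tissue class {montage[i].tissue!r} to average"
                )
            W[r, group] -= 1.0 / len(group)
        return W, [montage[i] for i in keep]

    if name == "esr":
        shafts: dict[str, list[int]] = {}
        for i in keep:
            shafts.setdefault(montage[i].shaft, []).append(i)
        out = []
        for i in keep:
            if len(shafts[montage[i].shaft]) >= 2:
                out.append(i)
            else:
                warnings.warn(
                    f"channel {montage[i].channel_id} excluded: single-contact "
                    "shaft cannot be shaft-referenced"
                )
        W = np.zeros((len(out), n_in))
        for r, i in enumerate(out):
            group = shafts[montage[i].shaft]
            W[r, i] += 1.0
            W[r, group] -= 1.0 / len(group)
        return W, [montage[i] for i in out]

    nb = _neighbors(montage, keep)

    if name == "bipolar":
        rows, out = [], []
        for i in keep:
            j = nb[i][1]  # next-superficial included neighbor
            if j is None:
                continue
            row = np.zeros(n_in)
            row[i] = 1.0
            row[j] = -1.0
            rows.append(row)
            deep, sup = montage[i], montage[j]
            out.append(
                ChannelInfo(
                    channel_id=f"{deep.channel_id}-{sup.channel_id}",
                    shaft=deep.shaft,
                    contact_index=deep.contact_index,
                    tissue=deep.tissue,
                    coords=deep.coords,
                )
            )
        if not rows:
            raise ValueError("no adjacent contact pairs for bipolar reference")
        return np.array(rows), out

    if name == "laplacian":
        rows, out = [], []
        for i in keep:
            lo, hi = nb[i]
            row = np.zeros(n_in)
            row[i] = 1.0
            if lo is not None and hi is not None:
                row[lo] -= 0.5
                row[hi] -= 0.5
            elif scheme.edge_policy == "single_neighbor" and (
                    lo is not None or hi is not None):
                row[lo if lo is not None else hi] -= 1.0
            else:
                continue  # drop_ends, or isolated contact
            rows.append(row)
            out.append(montage[i])
        if not rows:
            raise ValueError("no referencable contacts for Laplacian reference")
        return np.array(rows), out

    raise ValueError(f"unknown scheme {name!r}")  # pragma: no cover


def _apply_matrix(W, data):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        return W @ data
    if data.ndim == 3:
        return np.einsum("oc,tcs->tos", W, data, optimize=True)
    raise ValueError("data must be 2-D or 3-D")


def _run(name, data, montage, excluded=None, edge_policy="single_neighbor"):
    scheme = RerefScheme(name, edge_policy=edge_policy,
                         excluded_channels=frozenset(excluded or ()))
    W, out = reref_matrix(scheme, montage)
    return _apply_matrix(W, data), out


def apply_car(data, montage, excluded=None):
    """Subtract the common average of all included channels."""
    out_data, _ = _run("car", data, montage, excluded)
    return out_data


def apply_gwr(data, montage, excluded=None):
    """Subtract the gray-matter average from gray channels and the
    white-matter average from white channels."""
    out_data, _ = _run("gwr", data, montage, excluded)
    return out_data


def apply_esr(data, montage, excluded=None):
    """Subtract, per electrode shaft, the average of that shaft's channels."""
    out_data, _ = _run("esr", data, montage, excluded)
    return out_data


def apply_bipolar(data, montage, excluded=None):
    """Adjacent-contact differences (deep minus superficial).

    Returns ``(data', derived_montage)``; each derived channel records the
    contact pair in its channel_id and inherits the deep contact's position.
    """
    return _run("bipolar", data, montage, excluded)


def apply_laplacian(data, montage, excluded=None, edge_policy="single_neighbor"):
    """Subtract the mean of the two shaft neighbors (interior contacts);
    end contacts per ``edge_policy``."""
    out_data, _ = _run("laplacian", data, montage, excluded, edge_policy)
    return out_data


def apply_scheme(obj, scheme: RerefScheme | str):
    """Re-reference an EpochSet or Recording under ``scheme``.

    Returns the same container type with transformed data and the derived
    montage; ``raw`` is the identity on included channels.
    """
    if isinstance(scheme, str):
        scheme = RerefScheme(scheme)
    if isinstance(obj, EpochSet):
        W, out_montage = reref_matrix(scheme, obj.montage)
        return obj.with_data(_apply_matrix(W, obj.data), out_montage)
    from .io_montage import Recording

    if isinstance(obj, Recording):
        W, out_montage = reref_matrix(scheme, obj.montage)
        return Recording(data=_apply_matrix(W, obj.data), fs=obj.fs,
                         montage=out_montage, emg=obj.emg,
                         line_freq=obj.line_freq)
    raise TypeError("apply_scheme expects an EpochSet or Recording")
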