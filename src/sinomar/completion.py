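"""Sinogram completion: view decimation, angular up-sampling, linear
interpolation of missing data, and patch-based synthesis with the modified
U-Net.

The completion chain for a sparse-view scan with a metal marker is:
up-sample the view grid (inserted views invalid) -> flag the metal trace
invalid -> fill every invalid entry by linear interpolation -> optionally
refine the filled entries with the trained sinogram network.  Measured bins
are never overwritten: after network synthesis the originally valid entries
are restored verbatim.
"""

from __future__ import annotations

import numpy as np

from .geometry import ScanGeometry, Sinogram

__all__ = [
    "downsample_views",
    "upsample_view_grid",
    "linear_interpolate",
    "angular_fill",
    "sinogram_network_input",
    "unet_synthesize",
    "guarded_synthesize",
    "tile_apply",
]


class CompletionError(ValueError):
    pass


def downsample_views(sinogram: Sinogram, factor: int) -> Sinogram:
    """Keep every ``factor``-th view (indices 0, factor, 2*factor, ...).

    The geometry's angular step is scaled by the factor; e.g. a 360-view
    1-degree scan decimated by 4 becomes a 90-view 4-degree scan.
    """
    if factor < 1:
        raise CompletionError("factor must be a positive integer")
    if sinogram.geometry.n_views % factor:
        raise CompletionError(
            f"decimation factor {factor} does not divide n_views={sinogram.geometry.n_views}"
        )
    if factor == 1:
        return sinogram.copy()
    g = sinogram.geometry
    new_geom = ScanGeometry(
        n_views=g.n_views // factor,
        angle_step_deg=g.angle_step_deg * factor,
        n_bins=g.n_bins,
        bin_spacing=g.bin_spacing,
        image_size=g.image_size,
        pixel_size=g.pixel_size,
    )
    return Sinogram(
        sinogram.values[:, ::factor].copy(), new_geom, sinogram.valid_mask[:, ::factor].copy()
    )


def upsample_view_grid(sinogram: Sinogram, factor: int) -> Sinogram:
    """Insert ``factor - 1`` empty views between consecutive measured views.

    Measured views are copied at their positions (valid); inserted views are
    zero-filled and flagged invalid.  A 90-view scan up-sampled by 4 becomes a
    360-view grid with 270 invalid views.
    """
    if factor < 1:
        raise CompletionError("factor must be a positive integer")
    if factor == 1:
        return sinogram.copy()
    g = sinogram.geometry
    new_geom = ScanGeometry(
        n_views=g.n_views * factor,
        angle_step_deg=g.angle_step_deg / factor,
        n_bins=g.n_bins,
        bin_spacing=g.bin_spacing,
        image_size=g.image_size,
        pixel_size=g.pixel_size,
    )
    values = np.zeros((g.n_bins, new_geom.n_views), dtype=np.float64)
    mask = np.zeros_like(values, dtype=bool)
    values[:, ::factor] = sinogram.values
    mask[:, ::factor] = sinogram.valid_mask
    return Sinogram(values, new_geom, mask)


def _interp_periodic(positions: np.ndarray, known_pos: np.ndarray, known_val: np.ndarray, period: int) -> np.ndarray:
    """Linear interpolation on a periodic axis (views wrap at 360 degrees)."""
    ext_pos = np.concatenate([known_pos - period, known_pos, known_pos + period])
    ext_val = np.concatenate([known_val, known_val, known_val])
    return np.interp(positions, ext_pos, ext_val)


def linear_interpolate(sinogram: Sinogram) -> Sinogram:
    """Fill every invalid sinogram entry by linear interpolation.

    Entirely missing views are filled along the angular direction with
    360-degree wrap-around (views are periodic for a full scan).  Invalid
    bins inside otherwise-valid views (metal tracks) are filled first, along
    the detector direction within each view.  Valid entries are returned
    unchanged; the result is fully valid.
    """
    values = sinogram.values.copy()
    mask = sinogram.valid_mask.copy()
    n_bins, n_views = values.shape
    view_has_valid = mask.any(axis=0)
    if not view_has_valid.any():
        raise CompletionError("sinogram has no valid data at all")

    # 1) metal-track gaps inside measured views: detector-direction interpolation
    bins = np.arange(n_bins)
    for v in np.flatnonzero(view_has_valid):
        col_mask = mask[:, v]
        if col_mask.all():
            continue
        known = np.flatnonzero(col_mask)
        values[~col_mask, v] = np.interp(bins[~col_mask], known, values[known, v])
        mask[:, v] = True

    # 2) fully missing views: angular interpolation with wrap-around
    missing_views = np.flatnonzero(~view_has_valid)
    if missing_views.size:
        known_views = np.flatnonzero(view_has_valid)
        for b in range(n_bins):
            values[b, missing_views] = _interp_periodic(
                missing_views, known_views, values[b, known_views], n_views
            )
    return Sinogram(values, sinogram.geometry, np.ones_like(mask))


def angular_fill(sinogram: Sinogram) -> np.ndarray:
    """Fill every invalid entry by linear interpolation along the *angular*
    direction only (periodic over 360 degrees), per detector row.

    This is the complementary classical fill to :func:`linear_interpolate`:
    detector-direction filling is superior where a metal trace blocks a bin
    over long view ranges (wires near the rotation center), angular filling
    where the blocked ranges are short (wires off-center).  The sinogram
    network receives both fills and learns to blend them locally.  Rows with
    no valid view at all fall back to zero (the caller overlays the primary
    fill there).
    """
    values = sinogram.values.copy()
    mask = sinogram.valid_mask
    n_bins, n_views = values.shape
    for b in range(n_bins):
        known = np.flatnonzero(mask[b])
        miss = np.flatnonzero(~mask[b])
        if miss.size == 0:
            continue
        if known.size == 0:
            values[b, miss] = 0.0
            continue
        values[b, miss] = _interp_periodic(miss, known, values[b, known], n_views)
    return values


def tile_apply(model, array: np.ndarray, patch_size: int, stride: int | None = None) -> np.ndarray:
    """Run a patch-to-patch model over a 2-D array with overlapping tiles.

    ``array`` is either ``(h, w)`` or ``(c, h, w)`` with channel 0 the value
    channel (further channels are auxiliary model inputs).  Tiles are laid on
    a ``stride`` grid (default patch_size // 2) with extra tiles flush
    against the right/bottom borders; overlapping predictions are blended by
    uniform averaging.  Returns the ``(h, w)`` prediction.
    """
    if stride is None:
        stride = max(1, patch_size // 2)
    array = np.asarray(array, dtype=np.float64)
    if array.ndim == 2:
        array = array[None]
    _, h, w = array.shape
    if h < patch_size or w < patch_size:
        raise CompletionError(
            f"array {array.shape} smaller than patch size {patch_size}"
        )

    def _starts(extent: int) -> np.ndarray:
        s = list(range(0, extent - patch_size + 1, stride))
        if s[-1] != extent - patch_size:
            s.append(extent - patch_size)
        return np.asarray(s)

    rows, cols = _starts(h), _starts(w)
    patches = np.stack(
        [array[:, r : r + patch_size, c : c + patch_size] for r in rows for c in cols]
    )  # (n, c, p, p)
    predicted = model.predict(patches)[:, 0]
    out = np.zeros((h, w), dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    k = 0
    for r in rows:
        for c in cols:
            out[r : r + patch_size, c : c + patch_size] += predicted[k]
            weight[r : r + patch_size, c : c + patch_size] += 1.0
            k += 1
    return out / weight


def _gap_lengths(invalid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry length of the contiguous invalid run containing it, along
    the detector axis (non-periodic) and the angular axis (periodic).  Valid
    entries get 0."""
    n_bins, n_views = invalid.shape
    det = np.zeros(invalid.shape)
    for v in range(n_views):
        col = invalid[:, v]
        b = 0
        while b < n_bins:
            if col[b]:
                e = b
                while e < n_bins and col[e]:
                    e += 1
                det[b:e, v] = e - b
                b = e
            else:
                b += 1
    ang = np.zeros(invalid.shape)
    for b in range(n_bins):
        row = invalid[b]
        if row.all():
            ang[b] = n_views
            continue
        # rotate so the row starts at a valid view; runs then never straddle
        # the 360-degree seam
        start = int(np.argmax(~row))
        rot = np.roll(row, -start)
        lengths = np.zeros(n_views)
        v = 0
        while v < n_views:
            if rot[v]:
                e = v
                while e < n_views and rot[e]:
                    e += 1
                lengths[v:e] = e - v
                v = e
            else:
                v += 1
        ang[b] = np.roll(lengths, start)
    return det, ang


def sinogram_network_input(
    sinogram: Sinogram,
    invalid_mask: np.ndarray,
    trace_mask: np.ndarray | None,
) -> np.ndarray:
    """The six input channels of the sinogram network.

    Channel 0: the primary fill (detector-direction across metal tracks,
    angular across missing views — the :func:`linear_interpolate` output,
    which the network's global residual passes through).  Channel 1: the
    all-angular alternative fill.  Channels 2 and 3: the inserted-view and
    metal-trace masks.  Channels 4 and 5: the normalized lengths of the
    invalid run each entry sits in, along the detector and angular axes.

    Rationale: the two missing-data kinds have error scales two orders of
    magnitude apart, the better classical fill is object-dependent (angular
    filling fails for wires near the rotation center, whose traces block a
    bin over long view ranges), and the reliability of each fill is governed
    by the gap length bridged — which a patch-local network cannot infer on
    its own.  Given both estimates, both masks and both gap maps, blending
    and correcting become patch-local decisions.
    """
    trace = (
        np.zeros_like(invalid_mask)
        if trace_mask is None
        else np.asarray(trace_mask, dtype=bool)
    )
    inserted = invalid_mask & ~trace
    masked = Sinogram(sinogram.values, sinogram.geometry, ~invalid_mask)
    alt = angular_fill(masked)
    rows_dead = ~(~invalid_mask).any(axis=1)
    if rows_dead.any():  # bins blocked at every view: only the primary fill exists
        alt[rows_dead] = sinogram.values[rows_dead]
    gap_det, gap_ang = _gap_lengths(invalid_mask)
    n_bins, n_views = invalid_mask.shape
    return np.stack(
        [
            sinogram.values,
            alt,
            inserted.astype(np.float64),
            trace.astype(np.float64),
            gap_det / n_bins,
            gap_ang / n_views,
        ]
    )


def unet_synthesize(
    sinogram: Sinogram,
    model,
    patch_size: int | None = None,
    stride: int | None = None,
    invalid_mask: np.ndarray | None = None,
    trace_mask: np.ndarray | None = None,
) -> Sinogram:
    """Refine a linear-interpolation-initialized sinogram with the trained
    sinogram network.

    ``sinogram`` must be fully valid (initialize with
    :func:`linear_interpolate` first).  ``invalid_mask`` marks the entries
    that were originally missing; only those are overwritten with the network
    prediction — measured bins are restored bit-identically.  Models trained
    with mask input channels additionally receive the missing-data masks:
    with ``in_channels == 3`` the inserted-view mask and the metal-trace mask
    (``trace_mask``) are separate channels, with ``in_channels == 2`` a
    single combined mask.  If ``invalid_mask`` is None the whole sinogram is
    replaced by the prediction (pure denoising mode; single-channel models
    only).
    """
    if not sinogram.fully_valid:
        raise CompletionError("sinogram must be linear-interpolation initialized first")
    if patch_size is None:
        patch_size = model.patch_size
    if stride is None:
        stride = max(1, patch_size // 4)  # heavy overlap averages out synthesis noise
    if patch_size % (2**model.depth):
        raise CompletionError(
            f"patch size {patch_size} not divisible by 2^depth={2**model.depth}"
        )
    if invalid_mask is not None:
        invalid_mask = np.asarray(invalid_mask, dtype=bool)
        if invalid_mask.shape != sinogram.values.shape:
            raise CompletionError("invalid_mask shape does not match sinogram")
    in_channels = getattr(model, "in_channels", 1)
    if in_channels > 1 and invalid_mask is None:
        raise CompletionError("this model requires the originally-missing mask")
    if in_channels == 6:
        net_input = sinogram_network_input(sinogram, invalid_mask, trace_mask)
    elif in_channels == 2:
        net_input = np.stack([sinogram.values, invalid_mask.astype(np.float64)])
    else:
        net_input = sinogram.values
    predicted = tile_apply(model, net_input, patch_size, stride)
    out = sinogram.copy()
    if invalid_mask is None:
        out.values = predicted
    else:
        out.values[invalid_mask] = predicted[invalid_mask]
    return out


def guarded_synthesize(
    sinogram: Sinogram,
    model,
    invalid_mask: np.ndarray,
    trace_mask: np.ndarray | None = None,
    margin: float = 0.02,
    fbp_config=None,
) -> tuple[Sinogram, bool]:
    """Network synthesis accepted only if it improves physical consistency.

    Runs :func:`unet_synthesize`, then scores both the initialized input and
    the synthesized output by reprojection consistency at the measured bins
    (see :func:`sinomar.recon.reprojection_consistency`).  The synthesis is
    kept only when its inconsistency is at least ``margin`` (relative) lower
    than the initialization's; otherwise the initialization is returned
    unchanged.  Returns ``(sinogram, used_network)``.

    Rationale: at small training scales a learned completion helps most
    scans but can corrupt an occasional one; the measured projections
    themselves provide a ground-truth-free check.
    """
    from .recon import reprojection_consistency

    syn = unet_synthesize(sinogram, model, invalid_mask=invalid_mask, trace_mask=trace_mask)
    measured = ~np.asarray(invalid_mask, dtype=bool)
    base = reprojection_consistency(sinogram, measured, fbp_config)
    cand = reprojection_consistency(syn, measured, fbp_config)
    if cand <= (1.0 - margin) * base:
        return syn, True
    return sinogram.copy(), False
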