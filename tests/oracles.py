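"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the vectorized/transform-based code paths of the
package: everything is a direct translation of the stated definitions,
looping over cells.
"""

import math

import numpy as np
import shapely


def brute_rasterize(units, grid):
    """Point-in-polygon of every cell centre; boundary ties to smaller id."""
    xs, ys = grid.cell_centers()
    out = np.full(grid.shape, grid.nodata)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            pt = shapely.Point(xs[r, c], ys[r, c])
            hits = sorted(u.unit_id for u in units
                          if u.geometry.covers(pt))
            if hits:
                out[r, c] = hits[0]
    return out


def brute_nibble(grid, mask):
    """Exhaustive nearest-valid-cell search, row-major tie-break."""
    valid = grid.valid_mask()
    vr, vc = np.nonzero(valid)
    out = grid.values.copy()
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if grid.values[r, c] != grid.nodata:
                continue
            if mask.values[r, c] == mask.nodata:
                continue
            d2 = (vr - r) ** 2 + (vc - c) ** 2
            best = d2.min()
            cand = np.nonzero(d2 == best)[0]
            # earliest in row-major scan order among equidistant donors
            ranks = vr[cand] * grid.n_cols + vc[cand]
            k = cand[np.argmin(ranks)]
            out[r, c] = grid.values[vr[k], vc[k]]
    return out


def brute_distance_to(binary):
    fr, fc = np.nonzero(binary.values == 1)
    out = np.empty(binary.shape)
    for r in range(binary.n_rows):
        for c in range(binary.n_cols):
            d2 = (fr - r) ** 2 + (fc - c) ** 2
            out[r, c] = math.sqrt(d2.min()) * binary.cell_size
    return out


def brute_focal_proportion(binary, radius):
    out = np.empty(binary.shape)
    cs = binary.cell_size
    reach = int(radius // cs) + 1
    for r in range(binary.n_rows):
        for c in range(binary.n_cols):
            ones = 0
            total = 0
            for rr in range(max(0, r - reach), min(binary.n_rows, r + reach + 1)):
                for cc in range(max(0, c - reach), min(binary.n_cols, c + reach + 1)):
                    if ((rr - r) ** 2 + (cc - c) ** 2) * cs * cs <= radius * radius:
                        total += 1
                        if binary.values[rr, cc] == 1:
                            ones += 1
            out[r, c] = ones / total
    return out


def brute_zonal(stack, unit_raster):
    """Naive per-unit loop: fsum means for continuous, counted mode for cls_."""
    from gridpop.covariates import parse_name

    ids = sorted(set(unit_raster.values[unit_raster.valid_mask()].astype(int)))
    table = {}
    for name in stack.names:
        fam, _ = parse_name(name)
        col = {}
        for uid in ids:
            vals = []
            for r in range(unit_raster.n_rows):
                for c in range(unit_raster.n_cols):
                    if unit_raster.values[r, c] == uid:
                        vals.append(stack[name].values[r, c])
            if fam == "cls":
                ones = sum(1 for v in vals if v == 1)
                col[uid] = 1.0 if ones * 2 > len(vals) else 0.0
            else:
                col[uid] = math.fsum(vals) / len(vals)
        table[name] = col
    return table


def brute_unit_sums(grid, unit_raster):
    ids = sorted(set(unit_raster.values[unit_raster.valid_mask()].astype(int)))
    sums = {}
    for uid in ids:
        vals = []
        for r in range(unit_raster.n_rows):
            for c in range(unit_raster.n_cols):
                if unit_raster.values[r, c] == uid:
                    v = grid.values[r, c]
                    vals.append(0.0 if v == grid.nodata else v)
        sums[uid] = math.fsum(vals)
    return sums


def brute_slope(dem):
    """Independent central/one-sided finite differences, degrees."""
    v = dem.values
    cs = dem.cell_size
    out = np.empty(dem.shape)
    for r in range(dem.n_rows):
        for c in range(dem.n_cols):
            if 0 < c < dem.n_cols - 1:
                dx = (v[r, c + 1] - v[r, c - 1]) / (2 * cs)
            elif c == 0:
                dx = (v[r, c + 1] - v[r, c]) / cs
            else:
                dx = (v[r, c] - v[r, c - 1]) / cs
            if 0 < r < dem.n_rows - 1:
                dy = (v[r + 1, c] - v[r - 1, c]) / (2 * cs)
            elif r == 0:
                dy = (v[r + 1, c] - v[r, c]) / cs
            else:
                dy = (v[r, c] - v[r - 1, c]) / cs
            out[r, c] = math.degrees(math.atan(math.hypot(dx, dy)))
    return out
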