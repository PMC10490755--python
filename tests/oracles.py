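"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: set-based cubical
complex counting, O(N^2) nearest-neighbour scans, and dense-matrix graph
convolution.
"""

import numpy as np


def solid_euler_characteristic(occ: np.ndarray) -> int:
    """Euler characteristic V - E + F - C of the occupied cubical complex,
    counted over unique lattice vertices/edges/faces/cells.

    For a voxel solid that is a 3-manifold with boundary, the boundary
    surface satisfies chi(surface) = 2 * chi(solid).
    """
    verts, edges, faces = set(), set(), set()
    cells = 0
    for z, y, x in zip(*np.nonzero(occ)):
        cells += 1
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    verts.add((x + dx, y + dy, z + dz))
        for axis in range(3):
            for a in (0, 1):
                for b in (0, 1):
                    e = [x, y, z]
                    e[(axis + 1) % 3] += a
                    e[(axis + 2) % 3] += b
                    edges.add((axis, tuple(e)))
            for side in (0, 1):
                f = [x, y, z]
                f[axis] += side
                faces.add((axis, tuple(f)))
    return len(verts) - len(edges) + len(faces) - cells


def _block_component_table() -> np.ndarray:
    """For each of the 256 occupancy patterns of a 2x2x2 cell block, whether
    the occupied octants form at most one face-connected component."""
    ok = np.zeros(256, dtype=bool)
    neighbours = [
        [j for j in range(8) if bin(i ^ j).count("1") == 1] for i in range(8)
    ]
    for pattern in range(256):
        cells = [i for i in range(8) if pattern >> i & 1]
        if not cells:
            ok[pattern] = True
            continue
        seen, stack = {cells[0]}, [cells[0]]
        while stack:
            c = stack.pop()
            for nb in neighbours[c]:
                if pattern >> nb & 1 and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        ok[pattern] = len(seen) == len(cells)
    return ok


_BLOCK_OK = _block_component_table()


def is_manifold_voxel_solid(occ: np.ndarray) -> bool:
    """True when the boundary surface of the solid is a 2-manifold: around
    every lattice vertex, both the occupied and the empty cells of the
    surrounding 2x2x2 block must be face-connected (this subsumes the
    diagonal-edge case)."""
    padded = np.pad(occ, 1).astype(bool)

    def shifted(dz, dy, dx):
        return padded[
            dz : padded.shape[0] - 1 + dz,
            dy : padded.shape[1] - 1 + dy,
            dx : padded.shape[2] - 1 + dx,
        ]

    pattern = np.zeros((padded.shape[0] - 1, padded.shape[1] - 1, padded.shape[2] - 1), dtype=np.uint8)
    for i in range(8):
        dz, dy, dx = i >> 2 & 1, i >> 1 & 1, i & 1
        pattern |= shifted(dz, dy, dx).astype(np.uint8) << i
    return bool(_BLOCK_OK[pattern].all() and _BLOCK_OK[255 ^ pattern].all())


def brute_force_nearest(P: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Index of the closest g for every p, ties to the lowest index."""
    d = np.linalg.norm(P[:, None, :] - G[None, :, :], axis=2)
    return d.argmin(axis=1)


def dense_graph_conv(F: np.ndarray, A: np.ndarray, w0: np.ndarray, w1: np.ndarray):
    """ReLU(F w0 + A F w1) with a dense adjacency matrix."""
    return np.maximum(F @ w0 + A @ (F @ w1), 0.0)
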