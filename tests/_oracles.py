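"""Independent brute-force oracles, coded separately from the package.

Everything here is deliberately loop-based, scalar math so that
agreement with the vectorised package implementations is a meaningful
cross-check rather than a tautology.
"""

import math


def cremer_pople_oracle(coords):
    """(Q, theta_deg, phi_deg) by direct evaluation of the defining sums.

    Mean plane through the geometric centre with normal R' x R''
    (the plane whose displacements carry no m=1 Fourier component),
    then the m=2 and alternating m=3 sums, all with explicit loops.
    """
    n = 6
    cx = sum(p[0] for p in coords) / n
    cy = sum(p[1] for p in coords) / n
    cz = sum(p[2] for p in coords) / n
    rel = [(p[0] - cx, p[1] - cy, p[2] - cz) for p in coords]
    rp = [0.0, 0.0, 0.0]
    rpp = [0.0, 0.0, 0.0]
    for j in range(n):
        s = math.sin(2 * math.pi * j / n)
        c = math.cos(2 * math.pi * j / n)
        for k in range(3):
            rp[k] += rel[j][k] * s
            rpp[k] += rel[j][k] * c
    nx = rp[1] * rpp[2] - rp[2] * rpp[1]
    ny = rp[2] * rpp[0] - rp[0] * rpp[2]
    nz = rp[0] * rpp[1] - rp[1] * rpp[0]
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / norm, ny / norm, nz / norm
    z = [rel[j][0] * nx + rel[j][1] * ny + rel[j][2] * nz for j in range(n)]
    q2c = 0.0
    q2s = 0.0
    q3 = 0.0
    for j in range(n):
        q2c += z[j] * math.cos(4 * math.pi * j / n)
        q2s -= z[j] * math.sin(4 * math.pi * j / n)
        q3 += z[j] * (-1.0) ** j
    q2c *= math.sqrt(2.0 / n)
    q2s *= math.sqrt(2.0 / n)
    q3 *= math.sqrt(1.0 / n)
    q2 = math.hypot(q2c, q2s)
    big_q = math.hypot(q2, q3)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / big_q))))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return big_q, theta, phi


def dihedral_oracle(p1, p2, p3, p4):
    """Signed dihedral in degrees via the explicit atan2 construction."""

    def sub(a, b):
        return (a[0] - b[0], a[1] - b[1], a[2] - b[2])

    def cross(a, b):
        return (a[1] * b[2] - a[2] * b[1],
                a[2] * b[0] - a[0] * b[2],
                a[0] * b[1] - a[1] * b[0])

    def dot(a, b):
        return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]

    b1 = sub(p2, p1)
    b2 = sub(p3, p2)
    b3 = sub(p4, p3)
    n1 = cross(b1, b2)
    n2 = cross(b2, b3)
    norm2 = math.sqrt(dot(b2, b2))
    y = dot(cross(n1, n2), tuple(c / norm2 for c in b2))
    x = dot(n1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def karplus_oracle(theta_deg, p1, p2, p3, p4, p5, p6, substituents):
    """Term-by-term evaluation of the substituent-adjusted Karplus form."""
    t = math.radians(theta_deg)
    j = p1 * math.cos(t) ** 2 + p2 * math.cos(t) + p3
    for dchi, xi in substituents:
        inner = xi * t + math.radians(p6 * abs(dchi))
        j += dchi * (p4 + p5 * math.cos(inner) ** 2)
    return j


def rmsd_rotation_grid_oracle(a, b, coarse_deg=12.0, refinements=4):
    """Best-fit RMSD by hierarchical grid search over rotations.

    Centres both structures, then scans Euler angles on progressively
    finer grids around the best cell.  Accurate to ~1e-3 Å RMSD for
    small rigid toys; slow by design.
    """

    def centred(x):
        n = len(x)
        cx = sum(p[0] for p in x) / n
        cy = sum(p[1] for p in x) / n
        cz = sum(p[2] for p in x) / n
        return [(p[0] - cx, p[1] - cy, p[2] - cz) for p in x]

    def rot_matrix(ax, ay, az):
        ca, sa = math.cos(ax), math.sin(ax)
        cb, sb = math.cos(ay), math.sin(ay)
        cc, sc = math.cos(az), math.sin(az)
        rx = ((1, 0, 0), (0, ca, -sa), (0, sa, ca))
        ry = ((cb, 0, sb), (0, 1, 0), (-sb, 0, cb))
        rz = ((cc, -sc, 0), (sc, cc, 0), (0, 0, 1))

        def matmul(m, n):
            return tuple(
                tuple(sum(m[i][k] * n[k][j] for k in range(3))
                      for j in range(3))
                for i in range(3)
            )

        return matmul(rz, matmul(ry, rx))

    def rmsd_at(a0, b0, angles):
        r = rot_matrix(*angles)
        total = 0.0
        for pa, pb in zip(a0, b0):
            rb = tuple(sum(r[i][k] * pb[k] for k in range(3))
                       for i in range(3))
            total += sum((pa[i] - rb[i]) ** 2 for i in range(3))
        return math.sqrt(total / len(a0))

    a0, b0 = centred(a), centred(b)
    best = (0.0, 0.0, 0.0)
    best_val = rmsd_at(a0, b0, best)
    step = math.radians(coarse_deg)
    ticks = int(2 * math.pi / step) + 1
    for i in range(ticks):
        for j in range(ticks):
            for k in range(ticks):
                ang = (i * step, j * step, k * step)
                v = rmsd_at(a0, b0, ang)
                if v < best_val:
                    best_val, best = v, ang
    for _ in range(refinements):
        step /= 4.0
        base = best
        for di in range(-4, 5):
            for dj in range(-4, 5):
                for dk in range(-4, 5):
                    ang = (base[0] + di * step, base[1] + dj * step,
                           base[2] + dk * step)
                    v = rmsd_at(a0, b0, ang)
                    if v < best_val:
                        best_val, best = v, ang
    return best_val


#: frozen canonical-conformer table for the d-pyranose circuit
#: (O5-C1-C2-C3-C4-C5), keyed by ideal (theta, phi); chair/boat/skew
#: entries and the 4H3 half-chair anchor follow the standard published
#: layout, the remaining envelope/half-chair names follow from the
#: displacement-sign rule applied by hand.
PYRANOSE_VERTEX_NAMES = {
    (0.0, 0.0): "4C1",
    (180.0, 0.0): "1C4",
    (90.0, 0.0): "3,OB", (90.0, 30.0): "3S1", (90.0, 60.0): "B1,4",
    (90.0, 90.0): "5S1", (90.0, 120.0): "2,5B", (90.0, 150.0): "2SO",
    (90.0, 180.0): "B3,O", (90.0, 210.0): "1S3", (90.0, 240.0): "1,4B",
    (90.0, 270.0): "1S5", (90.0, 300.0): "B2,5", (90.0, 330.0): "OS2",
    (54.7, 0.0): "OE", (54.7, 60.0): "E1", (54.7, 120.0): "2E",
    (54.7, 180.0): "E3", (54.7, 240.0): "4E", (54.7, 300.0): "E5",
    (125.3, 0.0): "3E", (125.3, 60.0): "E4", (125.3, 120.0): "5E",
    (125.3, 180.0): "EO", (125.3, 240.0): "1E", (125.3, 300.0): "E2",
    (50.8, 30.0): "OH1", (50.8, 90.0): "2H1", (50.8, 150.0): "2H3",
    (50.8, 210.0): "4H3", (50.8, 270.0): "4H5", (50.8, 330.0): "OH5",
    (129.2, 30.0): "3H4", (129.2, 90.0): "5H4", (129.2, 150.0): "5HO",
    (129.2, 210.0): "1HO", (129.2, 270.0): "1H2", (129.2, 330.0): "3H2",
}
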