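"""Least-squares conformal flattening of a developable surface patch.

A cylinder patch can be rolled flat without distortion, so its conformal
(angle-preserving) flattening is also area-preserving — this is the property
that makes planimetry on the unwrapped image meaningful. The script builds a
cylinder-patch mesh, minimises the conformal energy (the squared
Cauchy-Riemann residual, weighted by triangle area) subject to two pinned
boundary vertices, and compares the flattened area with the 3D area.
"""
import numpy as np

from woundmap import TriangleMesh, conformal_energy, lscm

r, arc, length, n = 4.0, 1.4, 6.0, 40
s, t = np.meshgrid(np.linspace(-arc * r / 2, arc * r / 2, n),
                   np.linspace(0, length, n))
V = np.column_stack([r * np.sin(s.ravel() / r), t.ravel(),
                     r * (np.cos(s.ravel() / r) - 1.0)])
tris = []
for j in range(n - 1):
    for i in range(n - 1):
        a = j * n + i
        tris.append((a, a + 1, a + n + 1))
        tris.append((a, a + n + 1, a + n))
mesh = TriangleMesh(V, np.array(tris))

uvmap = lscm(mesh)
print(f"cylinder patch: arc {np.degrees(arc):.0f} deg, "
      f"3D area {mesh.area():.4f} cm^2 (analytic {arc * r * length:.4f})")
print(f"conformal energy of the flattening: {uvmap.energy:.2e} "
      "(zero for an exactly conformal map)")
print(f"flattened uv area: {uvmap.area(mesh):.4f} cm^2 -> "
      f"area distortion {100 * (uvmap.area(mesh) / mesh.area() - 1):+.3f} %")
assert conformal_energy(mesh, uvmap) == uvmap.energy
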