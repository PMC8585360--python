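"""Evaluate the closed-form force laws at a typical cutting condition.

Builds the default 90°-cone diamond tool and bovine cortical-bone material,
then prints the indentation geometry and every normal-force law at 0.7 mm
uncut chip thickness, plus the tangential force at the three osteon cutting
angles.  Fz is the force pressing the tool into the bone; Fp is the force
resisting its forward motion; their ratio f_p(θ) is the ploughing
coefficient, which is strongly anisotropic.
"""

import boneplough as bp

tool = bp.ToolGeometry()           # 90 deg cone -> flank angle phi = 45 deg
mat = bp.BoneMaterial()            # E = 15 GPa, delta_s = 150 MPa, tau_s = 3 MPa
nmodel, amodel = bp.datasets.reference_coefficients()

h = 0.7  # uncut chip thickness, mm
state = bp.IndentationState.from_depth(h, tool)
print(f"depth h = {h} mm -> volume V = {state.V:.5f} mm^3, "
      f"diameter d = {state.d:.2f} mm")

print(f"elastic (Sneddon) law:   Fz = {bp.elastic_normal_force(h, mat, tool):8.1f} N")
print(f"yield-limited law:       Fz = {bp.yield_normal_force(h, mat, tool):8.2f} N")
print(f"depth-integrated law:    Fz = {bp.integrated_normal_force(h, mat, tool):8.2f} N")
print(f"calibrated power law:    Fz = {bp.empirical_normal_force(state.V, nmodel):8.1f} N")

for theta in (0.0, 45.0, 90.0):
    pred = bp.tangential_force(state.V, theta, nmodel, amodel)
    print(f"theta = {theta:4.0f} deg:  f_p = {pred.fp:.3f}   Fp = {pred.Fp:6.1f} N")
# f_p peaks at 45 deg to the osteon axis -- cutting diagonally across the
# Haversian systems costs about 4x the tangential force of cutting along them
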