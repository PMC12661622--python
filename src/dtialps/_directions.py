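"""Frozen 30-direction diffusion-encoding table.

Generated once by minimizing the antipodally symmetric electrostatic
repulsion energy on the unit sphere (L-BFGS-B from a fixed random start);
the tensor design matrix built from these directions at a single shell has
condition number 1.59 and a minimum angular separation of 25.6 degrees.
"""

import numpy as np

DIRECTIONS_30 = np.array(
    [
        (-0.173404, -0.389642, +0.904495),
        (+0.650983, +0.058470, +0.756837),
        (-0.293034, -0.761361, +0.578326),
        (-0.694019, +0.370559, +0.617271),
        (-0.017069, +0.979964, +0.198442),
        (-0.726712, +0.634850, +0.262402),
        (+0.559640, +0.541911, +0.627006),
        (-0.410035, -0.901290, +0.139811),
        (+0.265062, +0.328578, +0.906520),
        (-0.971419, -0.229574, +0.060341),
        (+0.872064, +0.280930, +0.400727),
        (+0.644620, -0.404107, +0.648970),
        (+0.162340, -0.654581, +0.738356),
        (-0.350390, +0.786749, +0.508185),
        (-0.516628, +0.021225, +0.855947),
        (+0.930421, -0.153644, +0.332731),
        (+0.089805, +0.730114, +0.677399),
        (-0.863921, -0.077981, +0.497553),
        (-0.432097, +0.901619, +0.019392),
        (-0.745472, -0.585170, +0.319134),
        (+0.455568, -0.779685, +0.429590),
        (+0.752242, +0.644786, +0.135580),
        (-0.589479, -0.410174, +0.695896),
        (+0.305693, -0.220346, +0.926283),
        (-0.073538, +0.056205, +0.995707),
        (-0.959496, +0.235857, +0.154074),
        (+0.035681, -0.954828, +0.295010),
        (+0.798328, -0.570320, +0.193413),
        (+0.388502, +0.859466, +0.332242),
        (-0.265396, +0.463319, +0.845518),
    ]
)
DIRECTIONS_30 /= np.linalg.norm(DIRECTIONS_30, axis=1, keepdims=True)
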