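"""PARAFAC of a reaction-monitoring diffusion cube.

Diffusion experiments repeated during a reaction give a three-way array
(time x gradient x frequency) that is trilinear when each species keeps
its spectrum: PARAFAC then returns, per species, its spectrum, its
diffusion decay and its concentration profile directly.
"""

import numpy as np

from nmrkit.core import DiffusionEncoding
from nmrkit.multiway import parafac
from nmrkit.simulate import LineSpec, gradient_array, make_reaction_cube

lines = [
    LineSpec(-0.6, 1.0, 3.0, component_id=0, D=5e-10),   # reactant
    LineSpec(0.0, 0.8, 3.0, component_id=1, D=2e-10),    # product
    LineSpec(0.6, 0.6, 3.0, component_id=2, D=0.8e-10),  # catalyst (constant)
]
enc = DiffusionEncoding(g=gradient_array(12, 0.6, 0.05, "equal_g2"))
tgrid = np.linspace(0.0, 1.0, 10)
conc = np.column_stack([np.exp(-2 * tgrid), 1 - np.exp(-2 * tgrid),
                        np.full(10, 0.5)])
cube, freq = make_reaction_cube(lines, enc, conc, n_freq=200,
                                noise_sigma=1e-5, seed=2)
print(f"reaction cube: {cube.shape} (time x gradient x frequency)")

# a tight stop tolerance matters here: correlated concentration profiles
# put ALS in a slow-convergence "swamp" where the fit looks converged
# long before the factors stop mixing
factors = parafac(cube, F=3, nonneg=True, seed=2, tol=1e-16, max_iter=20000)
print(f"fit: {factors.fit_percent:.4f} % in {factors.iterations} iterations")

# read the diffusion coefficient of each component off its decay loading
# with the package's Stejskal-Tanner fitter
from nmrkit.diffusion import fit_monoexp

for k in range(3):
    D = fit_monoexp(factors.B[:, k], enc).value
    print(f"component {k + 1}: D = {D:.3e} m^2/s, "
          f"concentration trend {np.round(factors.A[:, k] / factors.A[:, k].max(), 2)[:4]}...")
# the three loadings reproduce the simulated diffusion coefficients
# (5e-10 falling reactant, 2e-10 rising product, 0.8e-10 constant
# catalyst) and their concentration profiles without any prior assignment
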