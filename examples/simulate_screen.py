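"""Generate a synthetic multi-parametric RNAi screen with known ground truth.

Builds a 120-gene screen (~7 oligos/gene, 40 z-scored parameters, 30%
off-target oligos) around a scale-free network with two planted modules,
then prints its structure.  The printed counts describe the matrix D the
analysis modules consume: P rows (one per oligo) by N parameter columns.
"""

from impact import PlantedModule, SimulationConfig, generate_network, generate_screen

config = SimulationConfig(
    n_genes=120,
    planted_modules=(PlantedModule(6, 0), PlantedModule(5, 1)),
)
network = generate_network(config, rng_seed=1)
screen, truth = generate_screen(network, config, rng_seed=2)

print(f"network: {network.n_nodes} nodes, {network.n_edges} edges")
print(f"screen:  P = {screen.total_profiles} profiles, N = {screen.n_parameters} "
      f"parameters, {screen.n_genes} genes")
print(f"mean oligos per gene: {screen.total_profiles / screen.n_genes:.2f}")
n_ote = sum(truth.off_target.values())
print(f"off-target oligos: {n_ote} ({n_ote / screen.total_profiles:.0%})")
for i, members in enumerate(truth.module_members):
    print(f"planted module {i}: {', '.join(members)}")
# A planted gene's on-target oligos share the module archetype; its
# off-target oligos carry unrelated profile shapes, as in a real screen.
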