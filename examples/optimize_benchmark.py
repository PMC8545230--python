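"""Minimize a benchmark objective with the advanced squirrel search.

Runs ASSOA and the basic SS on the 10-dimensional sphere and prints the
final best fitness of each: values near zero mean the swarm homed in on the
global minimum at the origin.
"""

from assoa import ASSOAParams, SearchSpace, SSParams, run_optimizer

space = SearchSpace.box(10, -5.0, 5.0)

for name, params in [("assoa", ASSOAParams(n=30, t_m=200)), ("ss", SSParams(n=30, t_m=200))]:
    result = run_optimizer(name, space, "sphere", params, seed=1)
    print(
        f"{name:>5}: best fitness {result.best_fitness:.3e} "
        f"after {result.evaluations} evaluations "
        f"(curve starts {result.curve[0]:.2f}, ends {result.curve[-1]:.3e})"
    )
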