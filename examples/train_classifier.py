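"""Train the single-hidden-layer perceptron by metaheuristic weight search.

No backpropagation: ASSOA searches the flat weight vector in [-1, 1]^L,
guided by a smooth cross-entropy surrogate on the train+validation pool.
Prints the held-out test accuracy on a margin-separable task, where values
near 1.0 mean the evolved network recovered the separating boundary.
"""

from assoa import ASSOAParams, generate_separable, train_mlp_with_optimizer

data = generate_separable(200, 10, margin=1.0, seed=200)
result = train_mlp_with_optimizer(
    data, algorithm="assoa", params=ASSOAParams(n=30, t_m=100), seed=0
)
arch = result.model.arch
print(f"architecture {arch.n_in}-{arch.m_hidden}-{arch.n_out}, {arch.n_weights} weights")
print(f"final search fitness (cross-entropy): {result.optimizer.best_fitness:.4f}")
print(f"test accuracy: {result.test_accuracy:.3f}")
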