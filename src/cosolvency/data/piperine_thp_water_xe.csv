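# Equilibrium mole-fraction solubility of piperine in Transcutol-HP (THP) +
# water blends, 298.2-318.2 K, 0.1 MPa. m is the THP mass fraction of the
# solute-free solvent blend (m = 0 pure water, m = 1 pure THP).
m,T_K,x_e
0.0,298.2,1.03e-5
0.0,303.2,1.17e-5
0.0,308.2,1.31e-5
0.0,313.2,1.47e-5
0.0,318.2,1.59e-5
0.1,298.2,2.57e-5
0.1,303.2,2.85e-5
0.1,308.2,3.19e-5
0.1,313.2,3.55e-5
0.1,318.2,3.80e-5
0.2,298.2,6.20e-5
0.2,303.2,6.88e-5
0.2,308.2,7.61e-5
0.2,313.2,8.40e-5
0.2,318.2,9.01e-5
0.3,298.2,1.59e-4
0.3,303.2,1.71e-4
0.3,308.2,1.86e-4
0.3,313.2,1.99e-4
0.3,318.2,2.15e-4
0.4,298.2,3.71e-4
0.4,303.2,4.07e-4
0.4,308.2,4.42e-4
0.4,313.2,4.79e-4
0.4,318.2,5.09e-4
0.5,298.2,9.06e-4
0.5,303.2,9.80e-4
0.5,308.2,1.08e-3
0.5,313.2,1.16e-3
0.5,318.2,1.25e-3
0.6,298.2,2.23e-3
0.6,303.2,2.39e-3
0.6,308.2,2.56e-3
0.6,313.2,2.74e-3
0.6,318.2,2.88e-3
0.7,298.2,5.40e-3
0.7,303.2,5.74e-3
0.7,308.2,6.10e-3
0.7,313.2,6.51e-3
0.7,318.2,6.80e-3
0.8,298.2,1.35e-2
0.8,303.2,1.40e-2
0.8,308.2,1.47e-2
0.8,313.2,1.55e-2
0.8,318.2,1.63e-2
0.9,298.2,3.26e-2
0.9,303.2,3.37e-2
0.9,308.2,3.53e-2
0.9,313.2,3.70e-2
0.9,318.2,3.87e-2
1.0,298.2,7.88e-2
1.0,303.2,8.12e-2
1.0,308.2,8.44e-2
1.0,313.2,8.79e-2
1.0,318.2,9.10e-2
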