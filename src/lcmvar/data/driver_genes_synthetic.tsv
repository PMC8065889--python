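# Synthetic driver-gene list: reproduces the 85-driver /
# 1211-non-driver class sizes of the study panel. Only KRAS,
# TP53, ATRX, ERBB3, BRIP1 and CASP8 are real gene symbols;
# GPNL* symbols are synthetic panel fillers.
KRAS
TP53
ATRX
ERBB3
BRIP1
CASP8
GPNL0001
GPNL0002
GPNL0003
GPNL0004
GPNL0005
GPNL0006
GPNL0007
GPNL0008
GPNL0009
GPNL0010
GPNL0011
GPNL0012
GPNL0013
GPNL0014
GPNL0015
GPNL0016
GPNL0017
GPNL0018
GPNL0019
GPNL0020
GPNL0021
GPNL0022
GPNL0023
GPNL0024
GPNL0025
GPNL0026
GPNL0027
GPNL0028
GPNL0029
GPNL0030
GPNL0031
GPNL0032
GPNL0033
GPNL0034
GPNL0035
GPNL0036
GPNL0037
GPNL0038
GPNL0039
GPNL0040
GPNL0041
GPNL0042
GPNL0043
GPNL0044
GPNL0045
GPNL0046
GPNL0047
GPNL0048
GPNL0049
GPNL0050
GPNL0051
GPNL0052
GPNL0053
GPNL0054
GPNL0055
GPNL0056
GPNL0057
GPNL0058
GPNL0059
GPNL0060
GPNL0061
GPNL0062
GPNL0063
GPNL0064
GPNL0065
GPNL0066
GPNL0067
GPNL0068
GPNL0069
GPNL0070
GPNL0071
GPNL0072
GPNL0073
GPNL0074
GPNL0075
GPNL0076
GPNL0077
GPNL0078
GPNL0079
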