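# synthetic 74-node scale-free fixture network (no biological meaning)
F0000	F0001
F0000	F0002
F0000	F0003
F0000	F0004
F0000	F0005
F0000	F0006
F0000	F0007
F0000	F0017
F0000	F0023
F0000	F0024
F0000	F0034
F0000	F0050
F0000	F0056
F0001	F0003
F0001	F0005
F0001	F0007
F0001	F0008
F0001	F0009
F0001	F0015
F0001	F0021
F0001	F0022
F0001	F0035
F0001	F0044
F0001	F0057
F0001	F0069
F0002	F0010
F0002	F0012
F0002	F0014
F0002	F0029
F0002	F0062
F0003	F0004
F0003	F0006
F0003	F0008
F0003	F0009
F0003	F0011
F0003	F0013
F0003	F0014
F0003	F0025
F0003	F0047
F0003	F0059
F0004	F0042
F0005	F0011
F0005	F0012
F0005	F0013
F0005	F0015
F0005	F0018
F0005	F0019
F0005	F0048
F0005	F0051
F0005	F0060
F0005	F0066
F0006	F0017
F0006	F0018
F0006	F0037
F0006	F0042
F0007	F0020
F0007	F0022
F0007	F0033
F0007	F0037
F0007	F0048
F0007	F0062
F0008	F0010
F0008	F0026
F0009	F0032
F0009	F0038
F0010	F0016
F0011	F0019
F0011	F0028
F0011	F0032
F0011	F0040
F0011	F0045
F0011	F0049
F0012	F0039
F0012	F0058
F0012	F0073
F0013	F0023
F0013	F0031
F0013	F0067
F0015	F0016
F0015	F0028
F0015	F0061
F0016	F0030
F0016	F0031
F0016	F0047
F0017	F0027
F0017	F0034
F0017	F0063
F0017	F0064
F0019	F0020
F0019	F0024
F0019	F0025
F0019	F0045
F0019	F0054
F0019	F0069
F0020	F0021
F0020	F0030
F0020	F0072
F0021	F0026
F0021	F0052
F0023	F0027
F0023	F0033
F0023	F0036
F0023	F0040
F0023	F0041
F0023	F0044
F0023	F0064
F0024	F0058
F0024	F0073
F0026	F0029
F0026	F0055
F0026	F0070
F0028	F0039
F0028	F0041
F0028	F0046
F0028	F0059
F0028	F0067
F0030	F0036
F0030	F0054
F0031	F0057
F0031	F0072
F0033	F0035
F0033	F0046
F0033	F0060
F0034	F0038
F0037	F0043
F0037	F0068
F0037	F0070
F0038	F0043
F0038	F0053
F0038	F0068
F0044	F0050
F0044	F0056
F0045	F0053
F0046	F0049
F0046	F0052
F0046	F0063
F0047	F0055
F0047	F0071
F0048	F0051
F0048	F0061
F0050	F0071
F0057	F0065
F0060	F0065
F0065	F0066
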