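analysis	model	free_parameters	lnL	aicc_printed	weight_printed	percent_printed
stratified	DEC	2	-361.5730074	727.210	6.78645E-57	0
stratified	DEC+J	3	-257.5495221	521.227	3.63279E-12	0
stratified	DEC constraints	2	-368.641341	741.346	5.77969E-60	0
stratified	DEC+J constraints	3	-296.8981293	599.924	2.96045E-29	0
stratified	DEC constraints Lesser Sunda open	2	-356.8097945	717.683	7.9484E-55	0
stratified	DEC+J constraints Lesser Sunda open	3	-260.6508287	527.429	1.63441E-13	0
stratified	DEC+x allDist unconstrained	3	-348.4018278	702.931	1.26936E-51	0
stratified	DEC+J+x allDist unconstrained	4	-233.2309378	474.676	0.046627816	4
stratified	DEC+x constraints	3	-347.2869076	700.701	3.87069E-51	0
stratified	DEC+J+x constraints	4	-239.6466376	487.507	7.62679E-05	0
stratified	DEC+x constraints Lesser Sunda open	3	-337.8727214	681.873	4.74589E-47	0
stratified	DEC+J+x constraints Lesser Sunda open	4	-230.1653798	468.545	1	96
unstratified	DEC	2	-357.3507865	718.765	1.57771E-61	0
unstratified	DEC+J	3	-252.5532517	511.234	1.83143E-16	0
unstratified	DEC constraints	2	-362.479737	729.023	9.34442E-64	0
unstratified	DEC+J constraints	3	-292.0505998	590.229	1.2862E-33	0
unstratified	DEC constraints Lesser Sunda open	2	-349.6247388	703.313	3.57608E-58	0
unstratified	DEC+J constraints Lesser Sunda open	3	-252.0925651	510.313	2.90311E-16	0
unstratified	DEC+x allDist unconstrained	3	-337.6891775	681.506	1.94414E-53	0
unstratified	DEC+J+x allDist unconstrained	4	-219.0452023	446.304	0.023021246	2
unstratified	DEC+x constraints	3	-339.3845311	684.897	3.56816E-54	0
unstratified	DEC+J+x constraints	4	-230.6067985	469.428	2.19276E-07	0
unstratified	DEC+x constraints Lesser Sunda open	3	-335.597475	677.323	1.5745E-52	0
unstratified	DEC+J+x constraints Lesser Sunda open	4	-215.2738645	438.762	1	98
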