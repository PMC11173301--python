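# Synthetic three-component far-UV CD reference basis, version 1.
# Parametric Gaussian band model of canonical mean-residue-ellipticity
# shapes (deg cm^2 dmol^-1), tabulated 200-240 nm at 0.5 nm:
#   helix = 70000*G(190,8) - 36000*G(208,6.5) - 34000*G(222,7.5)
#   sheet = 35000*G(196,7) - 20000*G(217,9)
#   coil  = -45000*G(197,9) + 4000*G(220,12)
# where G(c,s) = exp(-((lambda-c)/s)^2 / 2). Not derived from any measured
# protein reference set; intended for reproducible desk-scale unmixing.
wavelength_nm,helix,sheet,coil
200.0,14708.146526,26368.338845,-41570.767266
200.5,10522.293395,24740.733506,-40654.486844
201.0,6365.745001,23000.825082,-39625.936745
201.5,2264.226896,21165.715061,-38493.488050
202.0,-1756.907891,19252.882172,-37266.250245
202.5,-5672.956061,17279.852282,-35953.943597
203.0,-9460.172053,15263.891166,-34566.765943
203.5,-13096.101590,13221.727920,-33115.256490
204.0,-16559.932655,11169.315136,-31610.159171
204.5,-19832.853152,9121.630171,-30062.288036
205.0,-22898.402310,7092.520009,-28482.397043
205.5,-25742.801293,5094.590373,-26881.056373
206.0,-28355.247606,3139.138073,-25268.537220
206.5,-30728.157949,1236.124025,-23654.706710
207.0,-32857.345042,-605.816898,-22048.934291
207.5,-34742.115839,-2379.334039,-20460.010678
208.0,-36385.281193,-4078.292729,-18896.080049
208.5,-37793.070481,-5697.685643,-17364.585921
209.0,-38974.948629,-7233.529821,-15872.230794
209.5,-39943.337325,-8682.755318,-14424.949368
210.0,-40713.246588,-10043.091012,-13027.894863
210.5,-41301.827109,-11312.952541,-11685.437745
211.0,-41727.857689,-12491.336566,-10401.175920
211.5,-42011.185278,-13577.724767,-9177.955340
212.0,-42172.137612,-14572.000031,-8017.899783
212.5,-42230.929871,-15474.376454,-6922.448520
213.0,-42207.087290,-16285.343885,-5892.400493
213.5,-42118.905019,-17005.626961,-4927.963646
214.0,-41982.964905,-17636.157910,-4028.808044
214.5,-41813.726375,-18178.061799,-3194.121477
215.0,-41623.205248,-18632.652487,-2422.666323
215.5,-41420.750439,-19001.437203,-1712.836520
216.0,-41212.924248,-19286.127521,-1062.713658
216.5,-41003.487510,-19488.654413,-470.121263
217.0,-40793.486562,-19611.185121,67.323450
217.5,-40581.434919,-19656.139756,552.160995
218.0,-40363.578992,-19626.205710,987.044679
218.5,-40134.234226,-19524.348299,1374.699656
219.0,-39886.175806,-19353.816326,1717.886195
219.5,-39611.066677,-19118.141633,2019.367271
220.0,-39299.904983,-18821.132047,2281.880479
220.5,-38943.473261,-18466.857448,2508.114170
221.0,-38532.772597,-18059.629044,2700.687661
221.5,-38059.426563,-17603.972177,2862.135274
222.0,-37516.041816,-17104.593281,2994.893927
222.5,-36896.514741,-16566.341778,3101.293964
223.0,-36196.276273,-15994.167892,3183.552887
223.5,-35412.469898,-15393.077437,3243.771629
224.0,-34544.060671,-14768.084734,3283.933031
224.5,-33591.875853,-14124.164798,3305.902176
225.0,-32558.580206,-13466.205957,3311.428235
225.5,-31448.591186,-12798.963963,3302.147540
226.0,-30267.941051,-12127.018604,3279.587584
226.5,-29024.094268,-11454.733692,3245.171701
227.0,-27725.729541,-10786.221185,3200.224190
227.5,-26382.496278,-10125.310048,3145.975707
228.0,-25004.755403,-9475.520304,3083.568738
228.5,-23603.314128,-8840.042584,3014.063036
229.0,-22189.163690,-8221.723316,2938.440908
229.5,-20773.228141,-7623.055560,2857.612270
230.0,-19366.131202,-7046.175366,2772.419412
230.5,-17977.986929,-6492.863402,2683.641441
231.0,-16618.218583,-5964.551491,2591.998377
231.5,-15295.408763,-5462.333628,2498.154896
232.0,-14017.182505,-4986.980971,2402.723730
232.5,-12790.123793,-4538.960236,2306.268747
233.0,-11619.724809,-4118.454920,2209.307717
233.5,-10510.366215,-3725.388755,2112.314817
234.0,-9465.325973,-3359.450776,2015.722888
234.5,-8486.813547,-3020.121451,1919.925479
235.0,-7576.025852,-2706.699302,1825.278731
235.5,-6733.221068,-2418.327510,1732.103101
236.0,-5957.806297,-2154.020062,1640.684986
236.5,-5248.435085,-1912.687012,1551.278260
237.0,-4603.111017,-1693.158529,1464.105739
237.5,-4019.293861,-1494.207439,1379.360625
238.0,-3494.005114,-1314.570039,1297.207905
238.5,-3023.930211,-1152.965030,1217.785758
239.0,-2605.515153,-1008.110443,1141.206953
239.5,-2235.055757,-878.738528,1067.560253
240.0,-1908.778210,-763.608584,996.911834
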