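group,nerve,measure_kind,unit,n_traditional,median_traditional,iqr_traditional,limit_traditional,pct_abnormal_traditional,n_enorms,median_enorms,iqr_enorms,limit_enorms,pct_abnormal_enorms
children_9_18,tibial,motor_amplitude,mV,63,13.5,5.2,7.5,27,1658,10.7,3.6,6.6,24
children_9_18,tibial,conduction_velocity,m/s,62,48.4,5.3,41.0,11,1419,48.1,4.2,43.0,16
children_9_18,tibial,f_min_latency,ms,63,39.4,7.4,51.8,9,1485,42.7,5.7,48.6,14
children_9_18,peroneal,motor_amplitude,mV,63,4.4,2.0,2.4,22,1683,4.1,1.5,2.2,20
children_9_18,peroneal,conduction_velocity,m/s,63,50.9,4.8,43.2,16,1414,48.8,4.1,43.4,17
children_9_18,peroneal,f_min_latency,ms,62,40.0,7.4,50.1,10,1321,42.1,5.7,46.7,19
children_9_18,sural,sensory_amplitude,µV,63,15.4,7.9,6.6,16,1301,14.3,6.5,7.3,18
children_9_18,sural,conduction_velocity,m/s,63,56.0,8.5,44.7,9,1271,54.2,6.5,46.3,12
children_9_18,superficial_peroneal,sensory_amplitude,µV,63,8.4,5.1,4.0,12,687,8.4,3.8,4.4,14
children_9_18,superficial_peroneal,conduction_velocity,m/s,63,53.4,6.8,44.3,11,1029,50.9,5.6,44.0,10
children_9_18,medial_plantar,sensory_amplitude,µV,63,10.1,5.9,3.8,13,228,8.4,3.7,4.3,15
children_9_18,medial_plantar,conduction_velocity,m/s,63,59.6,9.2,45.3,6,222,59.6,6.4,50.9,18
adults_20_44,tibial,motor_amplitude,mV,144,12.6,5.6,5.8,11,3169,10.6,4.0,5.9,11
adults_20_44,tibial,conduction_velocity,m/s,142,50.0,4.4,43.2,18,3121,48.2,4.5,44.1,22
adults_20_44,tibial,f_min_latency,ms,144,43.8,3.8,51.2,13,3223,44.6,4.0,49.7,19
adults_20_44,peroneal,motor_amplitude,mV,146,5.8,2.5,2.8,16,3272,5.1,1.8,2.9,17
adults_20_44,peroneal,conduction_velocity,m/s,145,48.5,3.3,43.1,19,3072,47.9,4.4,42.0,15
adults_20_44,peroneal,f_min_latency,ms,142,42.5,4.5,50.8,10,3051,43.3,4.5,49.0,16
adults_20_44,sural,sensory_amplitude,µV,146,11.7,8.8,2.6,6,2805,7.2,3.3,3.8,13
adults_20_44,sural,conduction_velocity,m/s,146,53.9,7.9,42.5,8,2798,51.9,7.5,42.9,9
adults_20_44,superficial_peroneal,sensory_amplitude,µV,122,8.3,6.1,2.9,7,767,8.0,3.7,4.1,15
adults_20_44,superficial_peroneal,conduction_velocity,m/s,122,52.2,7.1,43.0,19,758,48.3,5.3,41.8,13
adults_20_44,medial_plantar,sensory_amplitude,µV,122,8.8,7.5,1.2,10,1269,4.5,3.6,1.2,9
adults_20_44,medial_plantar,conduction_velocity,m/s,122,56.7,8.7,45.3,14,1268,54.2,5.8,46.6,18
adults_45_60,tibial,motor_amplitude,mV,150,10.7,5.7,4.0,20,4722,8.2,3.0,4.6,24
adults_45_60,tibial,conduction_velocity,m/s,150,48.1,5.6,40.7,24,4659,44.7,4.8,38.9,14
adults_45_60,tibial,f_min_latency,ms,148,45.9,5.1,55.5,14,4686,48.0,5.4,54.9,16
adults_45_60,peroneal,motor_amplitude,mV,149,5.8,2.1,2.2,23,4824,4.4,1.8,2.6,28
adults_45_60,peroneal,conduction_velocity,m/s,150,47.1,5.0,40.5,24,4549,44.6,4.9,38.6,16
adults_45_60,peroneal,f_min_latency,ms,145,44.6,5.9,53.2,17,4360,46.1,4.8,52.3,20
adults_45_60,sural,sensory_amplitude,µV,150,8.9,7.5,1.3,6,3925,5.4,2.5,2.9,20
adults_45_60,sural,conduction_velocity,m/s,150,52.0,8.1,42.7,18,3916,49.2,6.9,40.2,10
adults_45_60,superficial_peroneal,sensory_amplitude,µV,129,6.8,4.5,1.5,6,1024,5.1,2.6,2.4,12
adults_45_60,superficial_peroneal,conduction_velocity,m/s,129,52.0,6.2,40.4,18,1013,45.5,5.2,38.6,9
adults_45_60,medial_plantar,sensory_amplitude,µV,129,3.7,4.8,0.7,14,1639,2.3,1.9,0.8,19
adults_45_60,medial_plantar,conduction_velocity,m/s,129,54.4,9.1,40.9,10,1638,50.0,7.7,40.9,9
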