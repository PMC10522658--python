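cause,total,characteristic,level,count
alcohol_related,671625,age_group,0-24,58320
alcohol_related,671625,age_group,25-44,310415
alcohol_related,671625,age_group,45-64,271144
alcohol_related,671625,age_group,65+,31746
alcohol_related,671625,sex,female,246404
alcohol_related,671625,sex,male,425221
alcohol_related,671625,admission_type,inpatient,510449
alcohol_related,671625,admission_type,outpatient,161176
alcohol_related,671625,location,in_city,261944
alcohol_related,671625,location,not_in_city,409681
substance_related,721469,age_group,0-24,120077
substance_related,721469,age_group,25-44,373214
substance_related,721469,age_group,45-64,209459
substance_related,721469,age_group,65+,18719
substance_related,721469,sex,female,303549
substance_related,721469,sex,male,417920
substance_related,721469,admission_type,inpatient,535334
substance_related,721469,admission_type,outpatient,186135
substance_related,721469,location,in_city,305900
substance_related,721469,location,not_in_city,415569
cannabis,139240,age_group,0-24,52307
cannabis,139240,age_group,25-44,65870
cannabis,139240,age_group,45-64,20534
cannabis,139240,age_group,65+,529
cannabis,139240,sex,female,55322
cannabis,139240,sex,male,83918
cannabis,139240,admission_type,inpatient,94756
cannabis,139240,admission_type,outpatient,44484
cannabis,139240,location,in_city,45986
cannabis,139240,location,not_in_city,93254
cocaine,228989,age_group,0-24,20097
cocaine,228989,age_group,25-44,139053
cocaine,228989,age_group,45-64,68280
cocaine,228989,age_group,65+,1559
cocaine,228989,sex,female,89734
cocaine,228989,sex,male,139255
cocaine,228989,admission_type,inpatient,191250
cocaine,228989,admission_type,outpatient,37739
cocaine,228989,location,in_city,108318
cocaine,228989,location,not_in_city,120671
opioids,275707,age_group,0-24,34964
opioids,275707,age_group,25-44,145307
opioids,275707,age_group,45-64,89615
opioids,275707,age_group,65+,5821
opioids,275707,sex,female,116180
opioids,275707,sex,male,159527
opioids,275707,admission_type,inpatient,229442
opioids,275707,admission_type,outpatient,46265
opioids,275707,location,in_city,129607
opioids,275707,location,not_in_city,146100
sedatives,50068,age_group,0-24,5740
sedatives,50068,age_group,25-44,24812
sedatives,50068,age_group,45-64,17203
sedatives,50068,age_group,65+,2313
sedatives,50068,sex,female,23469
sedatives,50068,sex,male,26599
sedatives,50068,admission_type,inpatient,43352
sedatives,50068,admission_type,outpatient,6716
sedatives,50068,location,in_city,21799
sedatives,50068,location,not_in_city,28269
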